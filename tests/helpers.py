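"""Independent brute-force oracles used by the tests.

Each oracle is written as a direct, naive transcription of the defining
formulas (explicit loops, explicit set enumeration) so it shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import math


def oracle_normalized_weights(raw: dict[str, float]) -> dict[str, float]:
    vals = list(raw.values())
    mean = sum(vals) / 4.0
    var = sum((v - mean) ** 2 for v in vals) / 4.0
    sd = math.sqrt(var)
    return {k: (v - mean) / sd for k, v in raw.items()}


def oracle_composition(seq: str, lam: int, w: float, weights: dict[str, float]) -> list[float]:
    """Termwise evaluation of the pseudo-composition encoding."""
    seq = seq.upper().replace("T", "U")
    norm = oracle_normalized_weights(weights)
    L = len(seq)
    freqs = [seq.count(n) / L for n in "AGCU"]
    thetas = []
    for t in range(1, lam + 1):
        total = 0.0
        for i in range(L - t):
            total += (norm[seq[i]] - norm[seq[i + t]]) ** 2
        thetas.append(total / (L - t))
    denom = sum(freqs) + w * sum(thetas)
    # package order: A, G, C, U frequencies then order terms
    ordered = [seq.count(n) / L for n in "AGCU"]
    return [f / denom for f in ordered] + [w * th / denom for th in thetas]


def oracle_seqsim(vectors: list[list[float]]) -> list[list[float]]:
    """Min-max rescaled inverted Euclidean distances, diagonal 1."""
    n = len(vectors)

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    dists = [[dist(vectors[i], vectors[j]) for j in range(n)] for i in range(n)]
    off = [dists[i][j] for i in range(n) for j in range(n) if i != j]
    dmin, dmax = min(off), max(off)
    sim = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                sim[i][j] = 1.0 - (dists[i][j] - dmin) / (dmax - dmin)
    return sim


def oracle_pair_similarity(dis: float, mir: float, mode: str, avg_dis: float, avg_mir: float) -> float:
    if mode == "average":
        return (dis + mir) / 2.0
    if mode == "sqrt":
        return math.sqrt(dis * mir)
    if mode == "centre":
        return math.sqrt((dis - avg_dis) ** 2 + (mir - avg_mir) ** 2)
    raise ValueError(mode)


def oracle_score_pair(
    mirna_targets: dict[str, set[str]],
    mirna_diseases: dict[str, set[str]],
    disease_genes: dict[str, set[str]],
    all_diseases: set[str],
    r1: str,
    r2: str,
) -> dict[str, float]:
    """Direct set-enumeration of psg, rd, psgc and cfScore."""
    g1 = mirna_targets.get(r1, set())
    g2 = mirna_targets.get(r2, set())
    d1 = mirna_diseases.get(r1, set())
    d2 = mirna_diseases.get(r2, set())

    shared_g = g1 & g2
    psg = len(shared_g) / len(g1 | g2) if (g1 | g2) else 0.0

    shared_d = d1 & d2
    rd = 0.0
    if d1 | d2:
        rd = (len(shared_d) / len(d1 | d2)) * (len(shared_d) / len(all_diseases))

    if shared_g:
        covered = set()
        for d in shared_d:
            covered |= shared_g & disease_genes.get(d, set())
        psgc = len(covered) / len(shared_g)
    else:
        psgc = 0.0
    return {
        "psg": psg, "rd": rd, "psgc": psgc,
        "cf_score": psg * rd * psgc, "shared_diseases": len(shared_d),
    }


def oracle_target_probabilities(
    mirna_targets: dict[str, set[str]],
    mirna_diseases: dict[str, set[str]],
    disease_genes: dict[str, set[str]],
    r1: str,
    r2: str,
) -> dict[str, float]:
    shared_g = mirna_targets[r1] & mirna_targets[r2]
    shared_d = mirna_diseases.get(r1, set()) & mirna_diseases.get(r2, set())
    out = {}
    for g in shared_g:
        if shared_d:
            out[g] = sum(1 for d in shared_d if g in disease_genes.get(d, set())) / len(shared_d)
        else:
            out[g] = 0.0
    return out
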