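"""Shared test helpers: an independent alignment oracle, a structured random
hit-table generator, and a brute-force vote-count LCA oracle.

The oracles deliberately re-implement the logic with plain Python / pandas so
they share no code path with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from floramap.taxassign import AssignmentConfig, HitRecord

RANK_DEPTH = {"species": 3, "genus": 2, "family": 1, "unassigned": 0}


def fitting_align_oracle(a: str, b: str, match: int = 1, mismatch: int = -1,
                         gap: int = -2) -> tuple[int, int, int]:
    """Plain-python fitting alignment: query `a` global, subject `b` end-gap-free.

    Mirrors the documented tie-breaks (diagonal > up > left; endpoint = first
    maximum scanning the last row left to right).  Returns (score, matches,
    columns).
    """
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = S[i - 1][0] + gap
        P[i][0] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = S[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = S[i - 1][j] + gap
            left = S[i][j - 1] + gap
            best, ptr = d, 1
            if u > best:
                best, ptr = u, 2
            if left > best:
                best, ptr = left, 3
            S[i][j] = best
            P[i][j] = ptr
    bs, bj = None, 0
    for j in range(m + 1):
        if bs is None or S[n][j] > bs:
            bs, bj = S[n][j], j
    i, j, matches, cols = n, bj, 0, 0
    while i > 0:
        p = P[i][j]
        if p == 1:
            cols += 1
            matches += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return bs, matches, cols


def taxon_pool() -> list[tuple[str, str, str]]:
    pool = []
    for f in range(3):
        fam = f"Fam{f}"
        for g in range(2):
            gen = f"{fam}_Gen{g}"
            for s in range(3):
                pool.append((fam, gen, f"{gen}_sp{s}"))
    return pool


def random_hit_table(rng: np.random.Generator, qid: str = "Q1") -> list[HitRecord]:
    """Hits clustered around a true lineage, with identities straddling the
    97/95/90 rank thresholds and a spread of coverages."""
    pool = taxon_pool()
    true = pool[rng.integers(len(pool))]
    n = int(rng.integers(5, 41))
    qlen = int(rng.integers(40, 140))
    hits = []
    for i in range(n):
        u = rng.random()
        if u < 0.5:
            lin, ident = true, rng.uniform(96.5, 100.0)
        elif u < 0.7:
            sib = [p for p in pool if p[1] == true[1]]
            lin, ident = sib[rng.integers(len(sib))], rng.uniform(94.0, 98.5)
        elif u < 0.85:
            con = [p for p in pool if p[0] == true[0]]
            lin, ident = con[rng.integers(len(con))], rng.uniform(89.5, 97.0)
        else:
            lin, ident = pool[rng.integers(len(pool))], rng.uniform(80.0, 95.0)
        cov = rng.uniform(0.6, 1.0)
        alen = max(1, int(round(cov * qlen)))
        hits.append(HitRecord(
            query_id=qid, subject_id=f"ref{i:03d}", kingdom="Viridiplantae",
            family=lin[0], genus=lin[1], species=lin[2],
            identity=round(float(ident), 2), alignment_length=alen,
            query_length=qlen, score=round(float(ident) * alen / 100.0, 2)))
    return hits


def lca_vote_oracle(hits, config: AssignmentConfig = AssignmentConfig()
                    ) -> tuple[str, tuple]:
    """Brute-force pandas tally of the consensus-LCA rules."""
    df = pd.DataFrame([{
        "subject": h.subject_id, "kingdom": h.kingdom, "family": h.family,
        "genus": h.genus, "species": h.species, "identity": h.identity,
        "cov": h.alignment_length / h.query_length, "score": h.score,
    } for h in hits])
    df = df.sort_values(["score", "identity", "subject"],
                        ascending=[False, False, True], kind="stable")
    if len(df) > config.max_hits:
        cutoff = df["score"].iloc[config.max_hits - 1]
        df = df[df["score"] >= cutoff]
    df = df[df["cov"] > config.min_coverage]
    for rank, thr, cols in [("species", config.species_id, ["kingdom", "family", "genus", "species"]),
                            ("genus", config.genus_id, ["kingdom", "family", "genus"]),
                            ("family", config.family_id, ["kingdom", "family"])]:
        el = df[df["identity"] > thr]
        el = el[el[cols[-1]] != ""]
        if el.empty:
            continue
        counts = el.groupby(cols).size()
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        n_el = len(el)  # rank-eligible hits that carry a name at the rank
        if best[1] / n_el >= config.consensus:
            return rank, tuple(best[0])
    return "unassigned", ()
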