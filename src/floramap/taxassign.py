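"""Lowest-common-ancestor consensus taxonomy assignment for OTU centroids.

Similarity hits (BLAST-style tabular rows joined to reference lineages) are
filtered on coverage, truncated to the best 300, and voted rank by rank:
species requires >97% identity, genus >95%, family >90%, and an assignment at
a rank requires at least a 51% consensus of the rank-eligible hits on the full
lineage down to that rank.  OTUs matching no rank are unassigned; non-plant
kingdoms are removed before community analysis.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._align import semi_global
from .synthio import ReferenceRecord

__all__ = [
    "HitRecord",
    "AssignmentConfig",
    "Assignment",
    "load_hits",
    "search_internal",
    "lca_assign",
    "assign_all",
    "kingdom_filter",
    "assignment_rate",
]


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    kingdom: str
    family: str
    genus: str
    species: str
    identity: float          # percent, 0-100
    alignment_length: int    # alignment columns
    query_length: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of range: {self.identity}")

    @property
    def coverage(self) -> float:
        return self.alignment_length / self.query_length if self.query_length else 0.0


@dataclass(frozen=True)
class AssignmentConfig:
    max_hits: int = 300
    min_coverage: float = 0.80
    species_id: float = 97.0
    genus_id: float = 95.0
    family_id: float = 90.0
    consensus: float = 0.51

    def __post_init__(self) -> None:
        if not (self.species_id > self.genus_id > self.family_id):
            raise ValueError("rank thresholds must satisfy species > genus > family")
        if not 0.5 <= self.consensus <= 1.0:
            raise ValueError("consensus must lie in [0.5, 1]")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")

    def rank_thresholds(self) -> list[tuple[str, float]]:
        return [("species", self.species_id), ("genus", self.genus_id),
                ("family", self.family_id)]


@dataclass
class Assignment:
    otu_id: str
    resolved_rank: str                      # species | genus | family | unassigned
    kingdom: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    n_hits_used: int = 0

    def lineage(self) -> tuple[str, str, str, str]:
        return (self.kingdom, self.family, self.genus, self.species)


def load_hits(hits_path: str | Path, lineage_path: str | Path,
              query_lengths: Mapping[str, int] | None = None
              ) -> tuple[list[HitRecord], int]:
    """Parse an outfmt-6-like hit TSV plus a sidecar lineage TSV.

    The hit file must carry at least the 12 standard columns (qseqid sseqid
    pident length mismatch gapopen qstart qend sstart send evalue bitscore);
    a 13th column, when present, is read as the query length, otherwise
    `query_lengths` (e.g. from the centroid FASTA) supplies it, falling back
    to max(qstart, qend).  Rows that are malformed or whose subject has no
    lineage are skipped; the number skipped is returned alongside the records.
    """
    lineage = pd.read_csv(lineage_path, sep="\t", dtype=str).set_index("seq_id")
    records: list[HitRecord] = []
    skipped = 0
    with open(hits_path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            try:
                if len(row) < 12:
                    raise ValueError("short row")
                q, s = row[0], row[1]
                ident = float(row[2])
                alen = int(row[3])
                qstart, qend = int(row[6]), int(row[7])
                score = float(row[11])
                lin = lineage.loc[s]
                qlen = (int(row[12]) if len(row) > 12 else
                        (query_lengths or {}).get(q, max(qstart, qend)))
                records.append(HitRecord(
                    query_id=q, subject_id=s,
                    kingdom=str(lin["kingdom"]), family=str(lin["family"]),
                    genus=str(lin["genus"]), species=str(lin["species"]),
                    identity=ident, alignment_length=alen,
                    query_length=int(qlen), score=score))
            except (ValueError, KeyError):
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} malformed or lineage-less hit rows")
    records.sort(key=lambda h: (h.query_id, -h.score, -h.identity, h.subject_id))
    return records, skipped


def search_internal(centroids: Mapping[str, str], refdb: Sequence[ReferenceRecord]
                    ) -> list[HitRecord]:
    """All-vs-all semi-global search of centroids against the reference set.

    A BLAST-free similarity engine for synthetic data: every centroid is
    aligned to every reference with the shared overlap aligner, and the score
    is identity x alignment length (i.e. the number of matching columns).
    """
    if not refdb:
        raise ValueError("empty reference database")
    hits: list[HitRecord] = []
    for qid, qseq in centroids.items():
        for ref in refdb:
            aln = semi_global(qseq, ref.sequence)
            if aln.columns == 0:
                continue
            hits.append(HitRecord(
                query_id=qid, subject_id=ref.seq_id,
                kingdom=ref.kingdom, family=ref.family, genus=ref.genus,
                species=ref.species,
                identity=100.0 * aln.identity,
                alignment_length=aln.columns, query_length=len(qseq),
                score=float(aln.matches)))
    hits.sort(key=lambda h: (h.query_id, -h.score, -h.identity, h.subject_id))
    return hits


_RANK_DEPTH = {"species": 4, "genus": 3, "family": 2}


def lca_assign(hits: Sequence[HitRecord], config: AssignmentConfig = AssignmentConfig()
               ) -> Assignment:
    """Resolve one query's taxonomy by rank-wise consensus voting.

    Hits are truncated to the `max_hits` best by score (ties with the last
    kept score are all retained), filtered to coverage strictly above
    `min_coverage`, then voted from species downward: at each rank only hits
    with identity strictly above the rank threshold are eligible, and the
    query is assigned when at least a `consensus` fraction of them share the
    same lineage down to that rank.  Hits lacking a name at the rank under
    consideration do not vote at it.
    """
    if not hits:
        return Assignment(otu_id="", resolved_rank="unassigned")
    otu_id = hits[0].query_id
    ordered = sorted(hits, key=lambda h: (-h.score, -h.identity, h.subject_id))
    if len(ordered) > config.max_hits:
        cutoff = ordered[config.max_hits - 1].score
        ordered = [h for h in ordered if h.score >= cutoff]
    kept = [h for h in ordered if h.coverage > config.min_coverage]
    for rank, threshold in config.rank_thresholds():
        depth = _RANK_DEPTH[rank]
        eligible = [h for h in kept
                    if h.identity > threshold
                    and (h.kingdom, h.family, h.genus, h.species)[depth - 1]]
        if not eligible:
            continue
        votes = Counter()
        for h in eligible:
            votes[(h.kingdom, h.family, h.genus, h.species)[:depth]] += 1
        top_lin, top_n = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if top_n / len(eligible) >= config.consensus:
            padded = tuple(top_lin) + ("",) * (4 - depth)
            return Assignment(otu_id=otu_id, resolved_rank=rank,
                              kingdom=padded[0], family=padded[1],
                              genus=padded[2], species=padded[3],
                              n_hits_used=len(eligible))
    return Assignment(otu_id=otu_id, resolved_rank="unassigned")


def assign_all(hits: Iterable[HitRecord], config: AssignmentConfig = AssignmentConfig()
               ) -> list[Assignment]:
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [lca_assign(group, config) for _, group in sorted(by_query.items())]


def kingdom_filter(assignments: Sequence[Assignment],
                   keep_kingdom: str = "Viridiplantae"
                   ) -> tuple[list[Assignment], dict[str, int]]:
    """Retain plant assignments; report removals by kingdom/unassigned."""
    kept: list[Assignment] = []
    removed: Counter = Counter()
    for a in assignments:
        if a.resolved_rank == "unassigned":
            removed["unassigned"] += 1
        elif a.kingdom == keep_kingdom:
            kept.append(a)
        else:
            removed[a.kingdom] += 1
    return kept, dict(removed)


def assignment_rate(n_assigned: int, n_total: int) -> float:
    """Percentage of OTUs assigned at a rank, reported to one decimal."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_assigned <= n_total:
        raise ValueError("need 0 <= n_assigned <= n_total")
    return round(100.0 * n_assigned / n_total, 1)


def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    rows = [{"otu_id": a.otu_id, "rank": a.resolved_rank, "kingdom": a.kingdom,
             "family": a.family, "genus": a.genus, "species": a.species,
             "n_hits": a.n_hits_used} for a in assignments]
    return pd.DataFrame(rows, columns=["otu_id", "rank", "kingdom", "family",
                                       "genus", "species", "n_hits"])
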