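"""De novo chimera screening and greedy 97% centroid clustering.

Reads are dereplicated, screened for two-parent PCR chimeras, and clustered
greedily in decreasing-abundance order against previously founded centroids.
OTUs whose global read count is 1 (singletons) are excluded from the final
table, mirroring standard amplicon practice for the trnL P6 marker.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._align import match_profile, semi_global

__all__ = [
    "OTUTable",
    "pairwise_identity",
    "detect_chimeras",
    "greedy_cluster",
    "read_cleaned_fasta",
]


def pairwise_identity(a: str, b: str, match: int = 1, mismatch: int = -1,
                      gap: int = -2) -> tuple[float, int]:
    """Semi-global identity of query `a` fitted against subject `b`.

    Returns (identity fraction, alignment length in columns).  The query is
    aligned end to end; subject end gaps are free and excluded from the
    column count, while internal gaps count as columns.  Non-IUPAC
    characters raise ValueError.
    """
    aln = semi_global(a, b, match=match, mismatch=mismatch, gap=gap)
    return aln.identity, aln.columns


@dataclass
class OTUTable:
    """OTU x sample count matrix with centroid sequences and memberships."""

    counts: pd.DataFrame          # index otu_id, columns sample ids, int counts
    centroids: pd.Series          # otu_id -> centroid sequence
    members: dict[str, list[str]] = field(default_factory=dict)  # otu_id -> read ids
    n_singletons_dropped: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def total_count(self, otu_id: str) -> int:
        return int(self.counts.loc[otu_id].sum())

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="otu_id")

    def write_centroids_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for otu_id, seq in self.centroids.items():
                size = self.total_count(otu_id)
                fh.write(f">{otu_id};size={size}\n{seq}\n")

    @classmethod
    def read_tsv(cls, table_path: str | Path, centroid_fasta: str | Path | None = None
                 ) -> "OTUTable":
        counts = pd.read_csv(table_path, sep="\t", index_col="otu_id")
        centroids = pd.Series(dtype=object)
        if centroid_fasta is not None:
            from Bio import SeqIO

            seqs = {}
            for rec in SeqIO.parse(str(centroid_fasta), "fasta"):
                seqs[rec.id.split(";")[0]] = str(rec.seq)
            centroids = pd.Series(seqs).reindex(counts.index)
        return cls(counts=counts, centroids=centroids)


def _dereplicate(reads: Iterable[tuple[str, str, str]]):
    """Collapse (read_id, sample, sequence) records into unique sequences."""
    total: Counter = Counter()
    per_sample: dict[str, Counter] = {}
    read_ids: dict[str, list[str]] = {}
    samples: list[str] = []
    seen_samples = set()
    for read_id, sample, seq in reads:
        total[seq] += 1
        per_sample.setdefault(seq, Counter())[sample] += 1
        read_ids.setdefault(seq, []).append(read_id)
        if sample not in seen_samples:
            seen_samples.add(sample)
            samples.append(sample)
    return total, per_sample, read_ids, samples


def detect_chimeras(sequences: Sequence[str], abundances: Sequence[int],
                    min_parent_ratio: float = 2.0,
                    min_combined_identity: float = 0.99,
                    min_segment: int = 10) -> np.ndarray:
    """Flag putative two-parent chimeras among dereplicated sequences.

    A candidate is flagged iff some breakpoint splits it so that a left parent
    and a distinct right parent (each at least `min_parent_ratio` times as
    abundant as the candidate) jointly explain strictly more of its positions
    than any single parent does, with the combined identity over candidate
    positions at least `min_combined_identity`.  The 2x abundance skew follows
    the de novo chimera-screening convention for amplicon reads.  Breakpoints
    are only considered when both parent arms span at least `min_segment`
    positions: a terminal arm of a base or two carries no evidence of
    recombination and would let a coincidental match next to a point mutation
    masquerade as a chimera.
    """
    sequences = list(sequences)
    abundances = [int(a) for a in abundances]
    if len(sequences) != len(abundances):
        raise ValueError("sequences and abundances differ in length")
    if any(a < 1 for a in abundances):
        raise ValueError("abundances must be >= 1")
    flags = np.zeros(len(sequences), dtype=bool)
    for ci, cand in enumerate(sequences):
        parent_idx = [i for i, a in enumerate(abundances)
                      if i != ci and a >= min_parent_ratio * abundances[ci]]
        if len(parent_idx) < 2:
            continue
        L = len(cand)
        if L < 2 * min_segment:
            continue
        cums = {}
        best_single = 0
        cand_arr = np.frombuffer(cand.encode("ascii"), dtype=np.uint8)
        for pi in parent_idx:
            parent = sequences[pi]
            if len(parent) == L:
                # positional comparison is exact for the equal-length two-parent model
                prof = (cand_arr == np.frombuffer(parent.encode("ascii"),
                                                  dtype=np.uint8)).astype(np.int64)
            else:
                prof = match_profile(cand, parent).astype(np.int64)
            cum = np.concatenate([[0], np.cumsum(prof)])
            cums[pi] = cum
            best_single = max(best_single, int(cum[-1]))
        best_combined = 0
        for ai in parent_idx:
            ca = cums[ai]
            for bi in parent_idx:
                if bi == ai:
                    continue
                cb = cums[bi]
                # breakpoint k: left positions [0, k) from parent a, rest from b
                ks = np.arange(min_segment, L - min_segment + 1)
                joint = ca[ks] + (cb[L] - cb[ks])
                if joint.size:
                    best_combined = max(best_combined, int(joint.max()))
        if best_combined > best_single and best_combined / L >= min_combined_identity:
            flags[ci] = True
    return flags


def greedy_cluster(reads: Iterable[tuple[str, str, str]], threshold: float = 0.97,
                   keep_singletons: bool = False) -> OTUTable:
    """Abundance-ordered greedy centroid clustering of cleaned reads.

    `reads` yields (read_id, sample, sequence).  Unique sequences are sorted by
    decreasing abundance (ties broken lexicographically on the sequence) and
    each joins the first existing centroid with identity >= `threshold`,
    founding a new OTU otherwise.  OTUs with a global count of 1 are dropped
    unless `keep_singletons` is set; the number dropped is recorded.
    """
    total, per_sample, read_ids, samples = _dereplicate(reads)
    order = sorted(total, key=lambda s: (-total[s], s))
    centroid_seqs: list[str] = []
    assignment: list[int] = []  # per unique sequence, centroid index
    for seq in order:
        chosen = -1
        for idx, cen in enumerate(centroid_seqs):
            ident, _ = pairwise_identity(seq, cen)
            if ident >= threshold:
                chosen = idx
                break
        if chosen < 0:
            centroid_seqs.append(seq)
            chosen = len(centroid_seqs) - 1
        assignment.append(chosen)

    n_otus = len(centroid_seqs)
    counts = np.zeros((n_otus, len(samples)), dtype=np.int64)
    sample_pos = {s: i for i, s in enumerate(samples)}
    members: dict[int, list[str]] = {i: [] for i in range(n_otus)}
    for seq, cen_idx in zip(order, assignment):
        for sample, c in per_sample[seq].items():
            counts[cen_idx, sample_pos[sample]] += c
        members[cen_idx].extend(read_ids[seq])

    otu_ids = [f"OTU_{i + 1:05d}" for i in range(n_otus)]
    table = pd.DataFrame(counts, index=otu_ids, columns=samples)
    centroids = pd.Series(centroid_seqs, index=otu_ids)
    member_map = {otu_ids[i]: members[i] for i in range(n_otus)}

    n_dropped = 0
    if not keep_singletons:
        totals = table.sum(axis=1)
        keep = totals >= 2
        n_dropped = int((~keep).sum())
        table = table.loc[keep]
        centroids = centroids.loc[keep]
        member_map = {k: member_map[k] for k in table.index}
    return OTUTable(counts=table, centroids=centroids, members=member_map,
                    n_singletons_dropped=n_dropped)


def read_cleaned_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a cleaned-reads FASTA with `>readid;sample=S01` headers."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(";")
        sample = None
        for p in parts[1:]:
            if p.startswith("sample="):
                sample = p.split("=", 1)[1]
        if sample is None:
            raise ValueError(f"record {rec.id!r} lacks a sample= annotation")
        out.append((parts[0], sample, str(rec.seq)))
    return out
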