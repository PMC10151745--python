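"""Paired-end read cleaning: merging, demultiplexing, quality and length filters.

The cleaning cascade mirrors standard short-amplicon practice for the trnL P6
loop: pairs are merged first (with outie geometry allowed, so fully
overlapping palindrome pairs have their adapter read-through trimmed), then
demultiplexed on inline barcode + primer with one mismatch allowed on both
ends, then filtered on mean base quality (>30, computed on the retained
insert after trimming) and on insert length (>= 20 nt).  Pairs failing any
stage (orphans) never propagate, and a CleaningReport accounts for every
read's disposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthio import PRIMER_F, PRIMER_R, revcomp

__all__ = [
    "ReadPair",
    "MergedRead",
    "CleaningReport",
    "merge_pair",
    "demultiplex",
    "quality_filter",
    "length_filter",
    "clean_batch",
    "load_manifest",
]


@dataclass
class ReadPair:
    pair_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: Sequence[int]
    rev_qual: Sequence[int]
    assigned_sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.pair_id}: sequence and quality lengths differ")
        quals = list(self.fwd_qual) + list(self.rev_qual)
        if quals and (min(quals) < 0 or max(quals) > 60):
            raise ValueError(f"{self.pair_id}: Phred scores must lie in [0, 60]")


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    quality: np.ndarray
    overlap_mode: str          # "innie" | "outie"
    sample: str | None = None

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quality)) if len(self.quality) else 0.0


@dataclass
class CleaningReport:
    """Per-stage bookkeeping; kept + removed equals the stage input everywhere."""

    input_pairs: int = 0
    merged: int = 0
    orphans: int = 0
    assigned: int = 0
    ambiguous_barcode: int = 0
    unassigned: int = 0
    quality_passed: int = 0
    quality_failed: int = 0
    length_passed: int = 0
    length_failed: int = 0

    @property
    def cleaned(self) -> int:
        return self.length_passed

    def validate(self) -> None:
        assert self.input_pairs == self.merged + self.orphans
        assert self.merged == self.assigned + self.ambiguous_barcode + self.unassigned
        assert self.assigned == self.quality_passed + self.quality_failed
        assert self.quality_passed == self.length_passed + self.length_failed

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, getattr(self, k)) for k in (
            "input_pairs", "merged", "orphans", "assigned", "ambiguous_barcode",
            "unassigned", "quality_passed", "quality_failed", "length_passed",
            "length_failed")]
        rows.append(("cleaned", self.cleaned))
        return pd.DataFrame(rows, columns=["stage", "count"])


def merge_pair(pair: ReadPair, min_overlap: int = 10, min_identity: float = 0.75,
               allow_outie: bool = True) -> MergedRead | None:
    """Merge a read pair by scanning all innie and outie overlap offsets.

    The reverse mate is reverse-complemented and slid along the forward mate;
    the offset maximising matching bases (ties broken toward the longer merged
    insert, then toward the smaller offset) is accepted when the overlap spans
    at least `min_overlap` bases at `min_identity` identity.  Negative offsets
    are the outie geometry: the reverse-complemented mate starts before the
    forward one because the insert is shorter than the read, and the
    overhanging bases on both flanks are adapter read-through and are trimmed.
    Disagreeing overlap bases take the higher-quality base (forward wins ties).
    Returns None (orphan) when no acceptable overlap exists.
    """
    if not pair.fwd_seq or not pair.rev_seq:
        raise ValueError(f"{pair.pair_id}: empty mate")
    f = np.frombuffer(pair.fwd_seq.encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(revcomp(pair.rev_seq).encode("ascii"), dtype=np.uint8)
    fq = np.asarray(pair.fwd_qual, dtype=np.int16)
    rq = np.asarray(pair.rev_qual, dtype=np.int16)[::-1]
    lf, lr = f.size, r.size

    best = None  # (matches, merged_len, -offset)
    lo = -(lr - min_overlap) if allow_outie else 0
    for o in range(lo, lf - min_overlap + 1):
        start = max(0, o)
        end = min(lf, o + lr)
        k = end - start
        if k < min_overlap:
            continue
        matches = int((f[start:end] == r[start - o:end - o]).sum())
        if matches / k < min_identity:
            continue
        merged_len = max(lf, o + lr) if o >= 0 else k
        key = (matches, merged_len, -o)
        if best is None or key > best[0]:
            best = (key, o, start, end)
    if best is None:
        return None

    _, o, start, end = best
    # consensus over the overlap
    ov_f = f[start:end].copy()
    ov_fq = fq[start:end].copy()
    ov_r = r[start - o:end - o]
    ov_rq = rq[start - o:end - o]
    disagree = ov_f != ov_r
    take_r = disagree & (ov_rq > ov_fq)
    ov_f[take_r] = ov_r[take_r]
    ov_q = np.maximum(ov_fq, ov_rq)

    if o >= 0:
        left_s, left_q = f[:start], fq[:start]
        if o + lr >= lf:
            right_s, right_q = r[end - o:], rq[end - o:]
        else:  # reverse mate nested within forward
            right_s, right_q = f[end:], fq[end:]
        seq = np.concatenate([left_s, ov_f, right_s])
        qual = np.concatenate([left_q, ov_q, right_q])
        mode = "innie"
    else:
        seq, qual, mode = ov_f, ov_q, "outie"
    return MergedRead(read_id=pair.pair_id, sequence=seq.tobytes().decode("ascii"),
                      quality=qual.astype(np.int16), overlap_mode=mode)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(merged: MergedRead, barcode_map: Mapping[str, str],
                primer_fwd: str = PRIMER_F, primer_rev: str = PRIMER_R,
                max_mismatch: int = 1) -> tuple[str, MergedRead | None]:
    """Assign a merged read to a sample and trim barcode + primer from both ends.

    The merged amplicon is ``barcode + fwd primer + insert + rc(rev primer) +
    rc(barcode)``.  Assignment requires exactly one barcode within
    `max_mismatch` at each end (both agreeing) and both primers within
    `max_mismatch`.  Returns (status, trimmed read) with status one of
    "assigned", "ambiguous" or "unassigned"; the read is None unless assigned.
    """
    barcodes = dict(barcode_map)
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate barcodes in map")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must share one length")
    bl = lengths.pop()
    seq = merged.sequence
    pf, pr = primer_fwd, primer_rev
    if len(seq) < 2 * bl + len(pf) + len(pr) + 1:
        return "unassigned", None

    head_bc = seq[:bl]
    tail_bc = revcomp(seq[-bl:])
    head_hits = [s for s, b in barcodes.items() if _hamming(head_bc, b) <= max_mismatch]
    tail_hits = [s for s, b in barcodes.items() if _hamming(tail_bc, b) <= max_mismatch]
    if len(head_hits) > 1 or len(tail_hits) > 1:
        return "ambiguous", None
    if len(head_hits) != 1 or len(tail_hits) != 1 or head_hits[0] != tail_hits[0]:
        return "unassigned", None
    if _hamming(seq[bl:bl + len(pf)], pf) > max_mismatch:
        return "unassigned", None
    if _hamming(revcomp(seq[-(bl + len(pr)):-bl]), pr) > max_mismatch:
        return "unassigned", None

    lo = bl + len(pf)
    hi = len(seq) - bl - len(pr)
    trimmed = MergedRead(read_id=merged.read_id, sequence=seq[lo:hi],
                         quality=merged.quality[lo:hi],
                         overlap_mode=merged.overlap_mode, sample=head_hits[0])
    return "assigned", trimmed


def quality_filter(read: MergedRead, min_mean_quality: float = 30.0) -> bool:
    """Keep iff the arithmetic mean Phred over retained bases is strictly > 30."""
    if len(read.quality) == 0:
        return False
    return read.mean_quality > min_mean_quality


def length_filter(read: MergedRead, min_len: int = 20) -> bool:
    """Keep iff the primer-free insert is at least `min_len` nt."""
    return len(read.sequence) >= min_len


def load_manifest(path_or_frame) -> pd.DataFrame:
    """Load a sample manifest (sample, barcode, lat, lon, climate columns)."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        p = Path(path_or_frame)
        if not p.exists():
            raise FileNotFoundError(f"manifest not found: {p}")
        df = pd.read_csv(p)
    if "sample" not in df or "barcode" not in df:
        raise ValueError("manifest needs 'sample' and 'barcode' columns")
    if df["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in manifest")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    return df


def _iter_fastq_pairs(fwd_path, rev_path):
    from Bio import SeqIO

    fwd_iter = SeqIO.parse(str(fwd_path), "fastq")
    rev_iter = SeqIO.parse(str(rev_path), "fastq")
    idx = 0
    while True:
        try:
            frec = next(fwd_iter, None)
            rrec = next(rev_iter, None)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ near record {idx + 1}: {exc}") from exc
        if frec is None and rrec is None:
            return
        if frec is None or rrec is None:
            raise ValueError("forward and reverse FASTQ files have different lengths")
        idx += 1
        yield frec, rrec


def clean_batch(fwd_path, rev_path, manifest, min_overlap: int = 10,
                min_identity: float = 0.75, allow_outie: bool = True,
                max_mismatch: int = 1, min_mean_quality: float = 30.0,
                min_len: int = 20,
                primer_fwd: str = PRIMER_F, primer_rev: str = PRIMER_R
                ) -> tuple[list[MergedRead], CleaningReport]:
    """Run merge -> demultiplex -> quality -> length over paired FASTQ files."""
    man = load_manifest(manifest)
    barcode_map = dict(zip(man["sample"], man["barcode"]))
    report = CleaningReport()
    cleaned: list[MergedRead] = []
    for frec, rrec in _iter_fastq_pairs(fwd_path, rev_path):
        report.input_pairs += 1
        pair = ReadPair(frec.id, str(frec.seq), str(rrec.seq),
                        frec.letter_annotations["phred_quality"],
                        rrec.letter_annotations["phred_quality"])
        merged = merge_pair(pair, min_overlap=min_overlap, min_identity=min_identity,
                            allow_outie=allow_outie)
        if merged is None:
            report.orphans += 1
            continue
        report.merged += 1
        status, trimmed = demultiplex(merged, barcode_map, primer_fwd=primer_fwd,
                                      primer_rev=primer_rev, max_mismatch=max_mismatch)
        if status == "ambiguous":
            report.ambiguous_barcode += 1
            continue
        if status == "unassigned":
            report.unassigned += 1
            continue
        report.assigned += 1
        if not quality_filter(trimmed, min_mean_quality=min_mean_quality):
            report.quality_failed += 1
            continue
        report.quality_passed += 1
        if not length_filter(trimmed, min_len=min_len):
            report.length_failed += 1
            continue
        report.length_passed += 1
        cleaned.append(trimmed)
    report.validate()
    return cleaned, report


def write_cleaned_fasta(reads: Sequence[MergedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id};sample={read.sample}\n{read.sequence}\n")
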