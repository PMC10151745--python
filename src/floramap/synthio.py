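"""Synthetic inputs with the statistical structure the analysis assumes.

This module emulates a soil-eDNA plant metabarcoding study end to end:

* a nested kingdom/family/genus/species taxonomy;
* a reference database of short, variable-length trnL P6-loop marker
  sequences (default 30-143 nt) whose hierarchical divergence makes
  congeneric sequences more similar than confamilial ones;
* paired-end 2x150 bp reads with inline 8-mer barcodes and the trnL g/h
  primers, producing adapter read-through (palindrome) pairs whenever the
  amplicon is shorter than the read;
* a landscape of sampling sites on the sphere with climate covariates
  (MAT, MAP, SeaPrec) and spatially autocorrelated log-richness;
* gridded occurrence records and independent richness estimates standing in
  for aggregated-occurrence and expert-map products.

Every generator is deterministic under its seed, so downstream stages are
testable bit-for-bit without any external download.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "family", "genus", "species")
PLANT_KINGDOM = "Viridiplantae"

# trnL g/h primers amplifying the P6 loop of the trnL (UAA) intron
PRIMER_F = "GGGCAATCCTGAGCCAA"
PRIMER_R = "CCATTGAGTCTCTGCACCTATC"
# generic sequencing adapter used for read-through padding
ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGTAGCTAGCCTTCTGCTTGAAAGCAA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonomyNode:
    rank: str
    name: str
    parent: "TaxonomyNode | None"

    def lineage(self) -> tuple[str, ...]:
        node: TaxonomyNode | None = self
        names: list[str] = []
        while node is not None:
            names.append(node.name)
            node = node.parent
        return tuple(reversed(names))


@dataclass
class Taxonomy:
    """Strictly nested kingdom -> family -> genus -> species rank ladder."""

    kingdom: TaxonomyNode
    families: list[TaxonomyNode]
    genera: list[TaxonomyNode]
    species: list[TaxonomyNode]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def lineage_of(self, species_name: str) -> tuple[str, str, str, str]:
        for s in self.species:
            if s.name == species_name:
                k, f, g, sp = s.lineage()
                return k, f, g, sp
        raise KeyError(species_name)

    def lineage_table(self) -> pd.DataFrame:
        rows = [s.lineage() for s in self.species]
        return pd.DataFrame(rows, columns=list(RANKS))


_SYL = ["ba", "co", "da", "fe", "gi", "ho", "ju", "ka", "li", "mo",
        "na", "pe", "qui", "ra", "si", "tu", "ve", "xa", "yo", "zu"]


def _latinate(rng: np.random.Generator, n_syl: int) -> str:
    return "".join(rng.choice(_SYL) for _ in range(n_syl))


def make_taxonomy(n_families: int, genera_per_family: int, species_per_genus: int,
                  seed: int = 0, kingdom: str = PLANT_KINGDOM) -> Taxonomy:
    """Build a balanced taxonomy with the requested rank-wise fan-out."""
    for name, val in [("n_families", n_families), ("genera_per_family", genera_per_family),
                      ("species_per_genus", species_per_genus)]:
        if int(val) < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")
    rng = np.random.default_rng(seed)
    root = TaxonomyNode("kingdom", kingdom, None)
    families, genera, species = [], [], []
    gi = itertools.count()
    for fi in range(n_families):
        fam = TaxonomyNode("family", f"{_latinate(rng, 2).capitalize()}aceae_{fi:02d}", root)
        families.append(fam)
        for _ in range(genera_per_family):
            g = next(gi)
            gen = TaxonomyNode("genus", f"{_latinate(rng, 2).capitalize()}us_{g:03d}", fam)
            genera.append(gen)
            for si in range(species_per_genus):
                sp = TaxonomyNode("species", f"{gen.name} {_latinate(rng, 2)}_{si:02d}", gen)
                species.append(sp)
    return Taxonomy(kingdom=root, families=families, genera=genera, species=species)


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRecord:
    seq_id: str
    sequence: str
    lineage: tuple[str, str, str, str]  # kingdom, family, genus, species

    @property
    def kingdom(self) -> str:
        return self.lineage[0]

    @property
    def family(self) -> str:
        return self.lineage[1]

    @property
    def genus(self) -> str:
        return self.lineage[2]

    @property
    def species(self) -> str:
        return self.lineage[3]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each position independently with probability `rate`."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def make_reference_db(taxonomy: Taxonomy,
                      length_range: tuple[int, int] = (30, 143),
                      divergence: Mapping[str, float] | None = None,
                      completeness: float | Sequence[float] = 1.0,
                      seed: int = 0) -> list[ReferenceRecord]:
    """Generate marker sequences for a fraction of the taxonomy's species.

    Sequences are built hierarchically: each family gets a random ancestor of
    length drawn from `length_range`; genus ancestors mutate it at the
    ``family`` rate and species sequences mutate their genus ancestor at the
    ``genus`` rate, so congeneric records are on average more similar than
    confamilial ones.  Sequence content depends only on `taxonomy`, the length
    range, divergence and `seed` - calling with a lower `completeness` returns
    a deterministic subset of the complete database, which therefore serves as
    the ground truth for read simulation.

    `completeness` may be a scalar fraction (an exact species count is kept)
    or a per-species sequence of inclusion probabilities, which emulates
    geographically uneven reference-database coverage.
    """
    if taxonomy.n_species == 0:
        raise ValueError("empty taxonomy")
    divergence = dict(divergence or {"genus": 0.10, "family": 0.20})
    if divergence["genus"] >= divergence["family"]:
        raise ValueError("divergence must be ordered: within-genus < within-family")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")

    ss = np.random.SeedSequence(seed)
    rng_seq, rng_subset = [np.random.default_rng(s) for s in ss.spawn(2)]

    seqs: list[str] = []
    lineages: list[tuple[str, str, str, str]] = []
    for fam in taxonomy.families:
        L = int(rng_seq.integers(lo, hi + 1))
        fam_anc = _random_seq(rng_seq, L)
        for gen in (g for g in taxonomy.genera if g.parent is fam):
            gen_anc = _mutate(rng_seq, fam_anc, divergence["family"])
            for sp in (s for s in taxonomy.species if s.parent is gen):
                sp_seq = _mutate(rng_seq, gen_anc, divergence["genus"])
                seqs.append(sp_seq.tobytes().decode("ascii"))
                lineages.append(sp.lineage())

    n = len(seqs)
    if np.isscalar(completeness):
        frac = float(completeness)
        if not 0.0 <= frac <= 1.0:
            raise ValueError("completeness must be within [0, 1]")
        k = int(round(frac * n))
        keep = np.zeros(n, dtype=bool)
        keep[rng_subset.choice(n, size=k, replace=False)] = True
    else:
        probs = np.asarray(completeness, dtype=float)
        if probs.shape != (n,) or probs.min() < 0 or probs.max() > 1:
            raise ValueError("per-species completeness must be n_species probabilities in [0, 1]")
        keep = rng_subset.random(n) < probs

    return [ReferenceRecord(f"REF_{i:04d}", seqs[i], lineages[i])
            for i in range(n) if keep[i]]


def make_spikein_records(n: int, kingdom: str, length_range: tuple[int, int] = (60, 120),
                         seed: int = 0) -> list[ReferenceRecord]:
    """Random non-plant records (e.g. Fungi, Metazoa) for kingdom-filter tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_seq(rng, L).tobytes().decode("ascii")
        lin = (kingdom, f"{kingdom}aceae_{i:02d}", f"{kingdom}us_{i:02d}",
               f"{kingdom}us_{i:02d} sp_{i:02d}")
        out.append(ReferenceRecord(f"SPK_{kingdom[:3].upper()}_{i:03d}", seq, lin))
    return out


def write_reference_fasta(records: Sequence[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n{rec.sequence}\n")


def write_lineage_tsv(records: Sequence[ReferenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.seq_id, *r.lineage) for r in records],
        columns=["seq_id", *RANKS],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    lat: float
    lon: float
    mat: float       # mean annual temperature, degrees C
    map_mm: float    # mean annual precipitation, mm
    sea_prec: float  # precipitation seasonality, unitless


@dataclass
class Landscape:
    """Sampling sites with climate covariates and true plant richness."""

    sites: list[SiteRecord]
    true_richness: np.ndarray
    climate: pd.DataFrame          # index site_id, columns MAT/MAP/SeaPrec
    spatial_range: float           # autocorrelation decay scale, km
    seed: int
    noise: np.ndarray = field(default_factory=lambda: np.empty(0))
    site_species: dict[str, list[str]] | None = None
    taxonomy: Taxonomy | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def lats(self) -> np.ndarray:
        return np.array([s.lat for s in self.sites])

    @property
    def lons(self) -> np.ndarray:
        return np.array([s.lon for s in self.sites])

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]


def _haversine_matrix(lats: np.ndarray, lons: np.ndarray, radius_km: float = 6371.0
                      ) -> np.ndarray:
    la = np.radians(lats)[:, None]
    lb = np.radians(lats)[None, :]
    dlon = np.radians(lons)[:, None] - np.radians(lons)[None, :]
    h = np.sin((la - lb) / 2) ** 2 + np.cos(la) * np.cos(lb) * np.sin(dlon / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def make_landscape(n_sites: int = 40,
                   richness_model: tuple[float, float, float] = (2.5, 0.08, 0.0),
                   spatial_range: float = 1500.0,
                   noise_sd: float = 0.3,
                   seed: int = 0,
                   lat_range: tuple[float, float] = (35.0, 70.0),
                   lon_range: tuple[float, float] = (-10.0, 40.0),
                   taxonomy: Taxonomy | None = None,
                   niche_sd: float = 6.0) -> Landscape:
    """Place sites on the sphere and derive climate and true richness.

    True richness follows ``round(exp(b0 + b1*MAT + b2*MAP + eta))`` where
    ``eta`` is a zero-mean Gaussian field with exponential great-circle
    covariance of range `spatial_range` km and marginal SD `noise_sd`.  When a
    `taxonomy` is supplied, each species receives a thermal-niche optimum and
    every site draws its richness-many species preferentially from species
    whose optima sit near the site's MAT, giving communities climate-driven
    compositional turnover.
    """
    if n_sites < 10:
        raise ValueError("n_sites must be >= 10")
    if spatial_range < 0:
        raise ValueError("spatial_range must be non-negative")
    b0, b_mat, b_map = (float(v) for v in richness_model)
    ss = np.random.SeedSequence(seed)
    rng_geo, rng_clim, rng_field, rng_comm = [np.random.default_rng(s) for s in ss.spawn(4)]

    lats = rng_geo.uniform(*lat_range, n_sites)
    lons = rng_geo.uniform(*lon_range, n_sites)
    # latitudinal lapse plus site-level anomaly (continentality, topography):
    # real-world MAT at a fixed latitude spans several degrees C
    mat = 30.0 - 0.6 * np.abs(lats) + rng_clim.normal(0.0, 4.0, n_sites)
    map_mm = np.clip(300.0 + 25.0 * (70.0 - np.abs(lats)) + rng_clim.normal(0, 100, n_sites),
                     50.0, None)
    sea_prec = rng_clim.normal(0.0, 1.0, n_sites)

    if noise_sd > 0:
        if spatial_range > 0:
            D = _haversine_matrix(lats, lons)
            cov = noise_sd ** 2 * np.exp(-D / spatial_range)
            cov[np.diag_indices(n_sites)] += 1e-9
            noise = np.linalg.cholesky(cov) @ rng_field.standard_normal(n_sites)
        else:
            noise = rng_field.normal(0.0, noise_sd, n_sites)
    else:
        noise = np.zeros(n_sites)

    log_rich = b0 + b_mat * mat + b_map * map_mm + noise
    richness = np.maximum(1, np.round(np.exp(log_rich))).astype(int)
    if taxonomy is not None:
        richness = np.minimum(richness, taxonomy.n_species)

    site_ids = [f"S{i + 1:03d}" for i in range(n_sites)]
    sites = [SiteRecord(site_ids[i], float(lats[i]), float(lons[i]), float(mat[i]),
                        float(map_mm[i]), float(sea_prec[i])) for i in range(n_sites)]
    climate = pd.DataFrame({"MAT": mat, "MAP": map_mm, "SeaPrec": sea_prec}, index=site_ids)

    site_species = None
    if taxonomy is not None:
        names = taxonomy.species_names()
        optima = rng_comm.uniform(mat.min() - 2.0, mat.max() + 2.0, len(names))
        site_species = {}
        for i, sid in enumerate(site_ids):
            logw = -((mat[i] - optima) ** 2) / (2 * niche_sd ** 2)
            gumbel = rng_comm.gumbel(size=len(names))
            top = np.argsort(-(logw + gumbel), kind="stable")[: richness[i]]
            site_species[sid] = [names[j] for j in sorted(top)]

    return Landscape(sites=sites, true_richness=richness, climate=climate,
                     spatial_range=float(spatial_range), seed=int(seed), noise=noise,
                     site_species=site_species, taxonomy=taxonomy)


def write_manifest(landscape: Landscape, barcode_map: Mapping[str, str],
                   path: str | Path, realms: Mapping[str, str] | None = None) -> None:
    rows = []
    for s in landscape.sites:
        row = {
            "sample": s.site_id, "barcode": barcode_map[s.site_id],
            "lat": s.lat, "lon": s.lon, "MAT": s.mat, "MAP": s.map_mm,
            "SeaPrec": s.sea_prec,
        }
        if realms is not None:
            row["realm"] = realms[s.site_id]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# communities and reads
# ---------------------------------------------------------------------------

def make_communities(landscape: Landscape, reads_per_sample: int = 120,
                     min_count: int = 3, seed: int = 0) -> pd.DataFrame:
    """Species x sample read-abundance table from the landscape's communities.

    Present species get lognormal relative abundances scaled to roughly
    `reads_per_sample` reads per site, with a floor of `min_count` copies so
    genuinely present species survive singleton exclusion downstream.
    """
    if landscape.site_species is None:
        raise ValueError("landscape was built without a taxonomy; no communities to draw")
    rng = np.random.default_rng(np.random.SeedSequence([landscape.seed, 17, seed]))
    names = landscape.taxonomy.species_names()
    table = pd.DataFrame(0, index=names, columns=landscape.site_ids, dtype=int)
    for sid in landscape.site_ids:
        present = landscape.site_species[sid]
        w = rng.lognormal(0.0, 1.0, len(present))
        counts = np.maximum(min_count, np.round(w / w.sum() * reads_per_sample)).astype(int)
        table.loc[present, sid] = counts
    return table


def make_barcodes(samples: Sequence[str], length: int = 8, min_dist: int = 3,
                  seed: int = 0) -> dict[str, str]:
    """Unique fixed-length barcodes with pairwise Hamming distance >= `min_dist`."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    while len(chosen) < len(samples):
        cand = _random_seq(rng, length).tobytes().decode("ascii")
        if all(sum(a != b for a, b in zip(cand, c)) >= min_dist for c in chosen):
            chosen.append(cand)
    return dict(zip(samples, chosen))


def make_reads(community: pd.DataFrame,
               refdb: Sequence[ReferenceRecord],
               barcode_map: Mapping[str, str],
               error_rate: float = 0.005,
               read_length: int = 150,
               fail_fraction: float = 0.05,
               seed: int = 0):
    """Simulate paired 2x150 bp FASTQ records for a community table.

    Each amplicon is ``barcode + forward primer + insert + rc(reverse primer)
    + rc(barcode)``; when it is shorter than `read_length` both mates read
    through into the adapter, producing the palindrome/outie geometry.
    Per-base qualities are drawn so that about `fail_fraction` of pairs fall
    below the mean-Q30 retention rule.  Returns Biopython SeqRecord lists for
    both mates plus a per-read truth table.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq_by_species = {r.species: r.sequence for r in refdb}
    missing = [sp for sp in community.index
               if community.loc[sp].sum() > 0 and sp not in seq_by_species]
    if missing:
        raise ValueError(f"community species without reference sequence: {missing[:5]}")
    used = [sp for sp in community.index if community.loc[sp].sum() > 0]
    if not used:
        raise ValueError("empty community")
    min_insert = min(len(seq_by_species[sp]) for sp in used)
    if read_length < min_insert:
        raise ValueError(f"read_length {read_length} shorter than minimum insert {min_insert}")
    barcodes = dict(barcode_map)
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("barcodes must be unique")
    max_template = max(len(seq_by_species[sp]) for sp in used) + \
        len(PRIMER_F) + len(PRIMER_R) + 2 * len(next(iter(barcodes.values())))
    if 2 * read_length < max_template + 10:
        raise ValueError("read_length too short to merge the longest amplicon")

    rng = np.random.default_rng(seed)
    fwd_records, rev_records, truth = [], [], []
    counter = itertools.count(1)
    pad = ADAPTER * (1 + read_length // len(ADAPTER))
    for sample in community.columns:
        bc = barcodes[sample]
        for species in community.index:
            n_copies = int(community.at[species, sample])
            if n_copies == 0:
                continue
            insert = seq_by_species[species]
            template = bc + PRIMER_F + insert + revcomp(PRIMER_R) + revcomp(bc)
            fwd_t = (template + pad)[:read_length]
            rev_t = (revcomp(template) + pad)[:read_length]
            for _ in range(n_copies):
                rid = f"read{next(counter):07d}"
                fseq = _apply_errors(rng, fwd_t, error_rate)
                rseq = _apply_errors(rng, rev_t, error_rate)
                bad = rng.random() < fail_fraction
                centre = 25.0 if bad else 37.0
                fq = np.clip(np.round(rng.normal(centre, 2.0, read_length)), 2, 40).astype(int)
                rq = np.clip(np.round(rng.normal(centre, 2.0, read_length)), 2, 40).astype(int)
                frec = SeqRecord(Seq(fseq), id=rid, description="")
                frec.letter_annotations["phred_quality"] = fq.tolist()
                rrec = SeqRecord(Seq(rseq), id=rid, description="")
                rrec.letter_annotations["phred_quality"] = rq.tolist()
                fwd_records.append(frec)
                rev_records.append(rrec)
                truth.append({"read_id": rid, "sample": sample, "species": species,
                              "insert_len": len(insert), "low_quality": bad})
    return fwd_records, rev_records, pd.DataFrame(truth)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def write_fastq(records, path: str | Path) -> None:
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# occurrences and independent richness estimates
# ---------------------------------------------------------------------------

def make_occurrences(landscape: Landscape, detection: float = 1.0, grid=None
                     ) -> pd.DataFrame:
    """Gridded occurrence rows (species, family, cell_id) from the landscape.

    Each species truly present at a site is detected with probability
    `detection` and recorded in the site's grid cell.  `grid` must expose
    ``assign(lat, lon) -> cell_id`` (see geomapping.build_equal_area_grid);
    if omitted, each site is its own pseudo-cell.
    """
    if landscape.site_species is None:
        raise ValueError("landscape has no community composition")
    if not 0.0 <= detection <= 1.0:
        raise ValueError("detection must be within [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([landscape.seed, 29]))
    fam_of = {s.name: s.lineage()[1] for s in landscape.taxonomy.species}
    rows = []
    for site in landscape.sites:
        cell = grid.assign(site.lat, site.lon) if grid is not None else f"cell_{site.site_id}"
        for sp in landscape.site_species[site.site_id]:
            if rng.random() < detection:
                rows.append({"species": sp, "family": fam_of[sp], "cell_id": cell})
    df = pd.DataFrame(rows, columns=["species", "family", "cell_id"])
    return df.drop_duplicates().reset_index(drop=True)


def make_richness_estimates(landscape: Landscape, noise_sd: float = 0.25,
                            bandwidth_km: float = 800.0, seed: int = 0) -> pd.DataFrame:
    """Per-site stand-ins for independently mapped richness products.

    Emulates a cokriged expert map and a machine-learning ensemble estimate by
    perturbing log true richness and smoothing over nearby sites with a
    great-circle Gaussian kernel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([landscape.seed, 43, seed]))
    D = _haversine_matrix(landscape.lats, landscape.lons)
    W = np.exp(-0.5 * (D / bandwidth_km) ** 2)
    W /= W.sum(axis=1, keepdims=True)
    logr = np.log(landscape.true_richness.astype(float))
    out = {}
    for name in ("KreftJetz_cokrig", "Cai_ensemble"):
        noisy = logr + rng.normal(0.0, noise_sd, landscape.n_sites)
        out[name] = np.exp(W @ noisy)
    return pd.DataFrame(out, index=landscape.site_ids)


# ---------------------------------------------------------------------------
# bundled default scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    taxonomy: Taxonomy
    refdb: list[ReferenceRecord]
    landscape: Landscape
    community: pd.DataFrame
    barcode_map: dict[str, str]
    fwd_records: list
    rev_records: list
    truth: pd.DataFrame
    estimates: pd.DataFrame


def default_scenario(seed: int = 0, n_families: int = 6, genera_per_family: int = 3,
                     species_per_genus: int = 4, n_sites: int = 40,
                     reads_per_sample: int = 120, error_rate: float = 0.005,
                     fail_fraction: float = 0.05, completeness: float = 1.0
                     ) -> Scenario:
    """The fixed simulation scenario exercised by the integration suite."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(6) % (2 ** 31)]
    tax = make_taxonomy(n_families, genera_per_family, species_per_genus, seed=seeds[0])
    full_db = make_reference_db(tax, completeness=1.0, seed=seeds[1])
    refdb = (full_db if completeness >= 1.0
             else make_reference_db(tax, completeness=completeness, seed=seeds[1]))
    landscape = make_landscape(n_sites=n_sites, seed=seeds[2], taxonomy=tax)
    community = make_communities(landscape, reads_per_sample=reads_per_sample, seed=seeds[3])
    barcode_map = make_barcodes(landscape.site_ids, seed=seeds[4])
    fwd, rev, truth = make_reads(community, full_db, barcode_map, error_rate=error_rate,
                                 fail_fraction=fail_fraction, seed=seeds[5])
    estimates = make_richness_estimates(landscape)
    return Scenario(taxonomy=tax, refdb=refdb, landscape=landscape, community=community,
                    barcode_map=barcode_map, fwd_records=fwd, rev_records=rev,
                    truth=truth, estimates=estimates)
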