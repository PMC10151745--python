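"""Configuration and the end-to-end pipeline driver.

A single RunConfig (YAML-loadable, strictly validated) holds every stage
parameter with the study defaults: 10 bp / 75% merge overlap, 1-mismatch
demultiplexing, strict mean-Q30 retention, 20 bp minimum insert, 97%
clustering, up to 300 hits at >80% coverage with 97/95/90% rank thresholds
and 51% consensus, and 999 permutations for the constrained ordination.
`run_pipeline` chains simulate -> clean -> chimera/cluster -> assign ->
richness/VST -> correlations -> dbRDA -> mapping, logging per-stage counts
and writing a machine-readable JSON report; one master seed fans out to
per-stage child seeds so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import cluster as _cluster
from . import commstats, geomapping, ordination, readproc, spatialstats, synthio, taxassign

log = logging.getLogger("floramap")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateParams(_Strict):
    n_families: int = Field(6, ge=1)
    genera_per_family: int = Field(3, ge=1)
    species_per_genus: int = Field(4, ge=1)
    n_sites: int = Field(40, ge=10)
    reads_per_sample: int = Field(120, ge=10)
    error_rate: float = Field(0.005, ge=0.0, le=0.2)
    fail_fraction: float = Field(0.05, ge=0.0, le=1.0)
    completeness: float = Field(1.0, ge=0.0, le=1.0)


class MergeParams(_Strict):
    min_overlap: int = Field(10, ge=1)
    min_identity: float = Field(0.75, gt=0.0, le=1.0)
    allow_outie: bool = True


class DemuxParams(_Strict):
    max_mismatch: int = Field(1, ge=0)


class FilterParams(_Strict):
    min_mean_quality: float = Field(30.0, ge=0.0, le=60.0)
    min_length: int = Field(20, ge=1)


class ClusterParams(_Strict):
    threshold: float = Field(0.97, gt=0.5, le=1.0)


class AssignParams(_Strict):
    max_hits: int = Field(300, ge=1)
    min_coverage: float = Field(0.80, ge=0.0, le=1.0)
    species_id: float = Field(97.0, ge=0.0, le=100.0)
    genus_id: float = Field(95.0, ge=0.0, le=100.0)
    family_id: float = Field(90.0, ge=0.0, le=100.0)
    consensus: float = Field(0.51, ge=0.5, le=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.species_id > self.genus_id > self.family_id):
            raise ValueError("rank identity thresholds must satisfy species > genus > family")
        return self

    def to_config(self) -> taxassign.AssignmentConfig:
        return taxassign.AssignmentConfig(
            max_hits=self.max_hits, min_coverage=self.min_coverage,
            species_id=self.species_id, genus_id=self.genus_id,
            family_id=self.family_id, consensus=self.consensus)


class StatsParams(_Strict):
    n_distance_classes: int = Field(13, ge=2)


class OrdinationParams(_Strict):
    n_perm: int = Field(999, ge=99)


class MapParams(_Strict):
    n_grid_cells: int = Field(65612, ge=12)
    bandwidth_km: float = Field(800.0, gt=0.0)


class RunConfig(_Strict):
    seed: int = 0
    out_dir: Optional[str] = None
    manifest: Optional[str] = None
    log_level: str = "INFO"
    simulate: SimulateParams = SimulateParams()
    merge: MergeParams = MergeParams()
    demux: DemuxParams = DemuxParams()
    filter: FilterParams = FilterParams()
    cluster: ClusterParams = ClusterParams()
    assign: AssignParams = AssignParams()
    stats: StatsParams = StatsParams()
    ordination: OrdinationParams = OrdinationParams()
    map: MapParams = MapParams()


def validate_config(yaml_text: str) -> RunConfig:
    """Parse and range-check a YAML config; empty text yields all defaults."""
    data = yaml.safe_load(yaml_text) if yaml_text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    return RunConfig(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage on the synthetic scenario and emit a run report."""
    t0 = time.time()
    if config.manifest is not None and not Path(config.manifest).exists():
        raise FileNotFoundError(f"manifest not found: {config.manifest}")
    out = Path(out_dir or config.out_dir or "floramap_out")
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name: str, **counts):
        log.info("stage %-12s %s", name, counts)
        report["stages"][name] = counts

    # --- simulate -----------------------------------------------------------
    sim = config.simulate
    scen = synthio.default_scenario(
        seed=config.seed, n_families=sim.n_families,
        genera_per_family=sim.genera_per_family,
        species_per_genus=sim.species_per_genus, n_sites=sim.n_sites,
        reads_per_sample=sim.reads_per_sample, error_rate=sim.error_rate,
        fail_fraction=sim.fail_fraction, completeness=sim.completeness)
    synthio.write_fastq(scen.fwd_records, out / "reads_R1.fastq")
    synthio.write_fastq(scen.rev_records, out / "reads_R2.fastq")
    synthio.write_reference_fasta(scen.refdb, out / "reference.fasta")
    synthio.write_lineage_tsv(scen.refdb, out / "lineage.tsv")
    synthio.write_manifest(scen.landscape, scen.barcode_map, out / "manifest.csv")
    scen.truth.to_csv(out / "truth_reads.csv", index=False)
    stage("simulate", n_species=scen.taxonomy.n_species, n_sites=sim.n_sites,
          n_read_pairs=len(scen.fwd_records), n_references=len(scen.refdb))

    # --- clean --------------------------------------------------------------
    if config.manifest is not None:
        manifest = readproc.load_manifest(config.manifest)
    else:
        manifest = readproc.load_manifest(out / "manifest.csv")
    cleaned, clean_report = readproc.clean_batch(
        out / "reads_R1.fastq", out / "reads_R2.fastq", manifest,
        min_overlap=config.merge.min_overlap, min_identity=config.merge.min_identity,
        allow_outie=config.merge.allow_outie, max_mismatch=config.demux.max_mismatch,
        min_mean_quality=config.filter.min_mean_quality, min_len=config.filter.min_length)
    readproc.write_cleaned_fasta(cleaned, out / "cleaned.fasta")
    clean_report.to_frame().to_csv(out / "cleaning_report.csv", index=False)
    stage("clean", **{r.stage: int(r.count) for r in clean_report.to_frame().itertuples()})

    # --- chimera + cluster --------------------------------------------------
    reads = [(r.read_id, r.sample, r.sequence) for r in cleaned]
    from collections import Counter

    uniq = Counter(seq for _, _, seq in reads)
    seqs = sorted(uniq)
    flags = _cluster.detect_chimeras(seqs, [uniq[s] for s in seqs])
    chimeric = {s for s, f in zip(seqs, flags) if f}
    pd.DataFrame({"sequence": seqs, "abundance": [uniq[s] for s in seqs],
                  "chimera": flags}).to_csv(out / "chimera_report.csv", index=False)
    reads = [r for r in reads if r[2] not in chimeric]
    otus = _cluster.greedy_cluster(reads, threshold=config.cluster.threshold)
    otus.write_tsv(out / "otu_table.tsv")
    otus.write_centroids_fasta(out / "centroids.fasta")
    stage("cluster", n_chimeric_sequences=len(chimeric), n_otus=len(otus.otu_ids),
          n_singletons_dropped=otus.n_singletons_dropped)

    # --- assign -------------------------------------------------------------
    hits = taxassign.search_internal(dict(otus.centroids), scen.refdb)
    assignments = taxassign.assign_all(hits, config.assign.to_config())
    plant, removed = taxassign.kingdom_filter(assignments)
    taxassign.assignments_to_frame(assignments).to_csv(out / "assignments.tsv",
                                                       sep="\t", index=False)
    n_species_rank = sum(a.resolved_rank == "species" for a in assignments)
    stage("assign", n_otus=len(assignments), n_plant=len(plant),
          n_species_rank=n_species_rank,
          species_rate_pct=taxassign.assignment_rate(n_species_rank, max(1, len(assignments))),
          removed=removed)

    # --- richness metrics + comparison datasets ------------------------------
    plant_ids = [a.otu_id for a in plant]
    plant_table = _cluster.OTUTable(counts=otus.counts.loc[plant_ids],
                                    centroids=otus.centroids.loc[plant_ids])
    cleaned_per_site = pd.Series(Counter(r[1] for r in reads))
    rich = commstats.richness_metrics(plant_table, plant,
                                      cleaned_read_counts=cleaned_per_site)
    grid = geomapping.build_equal_area_grid(config.map.n_grid_cells)
    occ = synthio.make_occurrences(scen.landscape, detection=1.0, grid=grid)
    site_cells = pd.Series(grid.assign_many(scen.landscape.lats, scen.landscape.lons),
                           index=scen.landscape.site_ids)
    gbif_fam = occ.groupby("cell_id")["family"].nunique()
    gbif_sp = occ.groupby("cell_id")["species"].nunique()
    rich["GBIF_family"] = site_cells.map(gbif_fam).fillna(0).astype(int)
    rich["GBIF_species"] = site_cells.map(gbif_sp).fillna(0).astype(int)
    rich = rich.join(scen.estimates)
    rich.to_csv(out / "richness.csv")
    stage("richness", n_sites=len(rich), metrics=list(rich.columns))

    # --- correlations --------------------------------------------------------
    sites = pd.DataFrame({"lat": scen.landscape.lats, "lon": scen.landscape.lons},
                         index=scen.landscape.site_ids)
    n_classes = min(config.stats.n_distance_classes,
                    max(2, len(rich) * (len(rich) - 1) // 2 // 4))
    corr = spatialstats.correlation_matrix(rich, sites, n_classes=n_classes)
    corr.to_csv(out / "correlations.csv", index=False)
    stage("correlations", n_pairs=len(corr))

    # --- ordination ----------------------------------------------------------
    factors = commstats.size_factors(plant_table.counts)
    try:
        trend = commstats.fit_dispersion_trend(plant_table.counts, factors)
    except ValueError:
        trend = commstats.DispersionTrend(a0=1e-8, a1=0.0)
    vst_mat = commstats.vst(plant_table.counts, factors, trend)
    vst_mat.to_csv(out / "vst.tsv", sep="\t")
    dist = ordination.bray_curtis(ordination.nonneg_shift(vst_mat.T))
    climate = scen.landscape.climate.loc[dist.index]
    seeds = _child_seeds(config.seed, 4)
    ord_res = ordination.dbrda(dist, climate, n_perm=config.ordination.n_perm,
                               seed=seeds[0])
    pd.DataFrame({"eigenvalue": ord_res.eigenvalues}).to_csv(out / "eigenvalues.csv",
                                                             index=False)
    ord_res.site_scores.to_csv(out / "site_scores.csv")
    stage("ordination", constrained_inertia=ord_res.constrained_inertia,
          total_inertia=ord_res.total_inertia, permutation_p=ord_res.permutation_p)

    # --- mapping -------------------------------------------------------------
    sp_ref = {r.species for r in scen.refdb}
    per_site_cov = []
    for sid in scen.landscape.site_ids:
        obs = set(scen.landscape.site_species[sid])
        per_site_cov.append(geomapping.reference_coverage(obs, sp_ref) if obs else np.nan)
    cov_series = pd.Series(per_site_cov, index=scen.landscape.site_ids)
    smoothed, supported = geomapping.kernel_smooth_sphere(
        rich["eDNA_species"].to_numpy(), scen.landscape.lats, scen.landscape.lons,
        scen.landscape.lats, scen.landscape.lons, bandwidth_km=config.map.bandwidth_km)
    pd.DataFrame({
        "site": scen.landscape.site_ids, "lat": scen.landscape.lats,
        "lon": scen.landscape.lons, "smoothed_eDNA_species": smoothed,
        "supported": supported, "reference_coverage_pct": cov_series.to_numpy(),
    }).to_csv(out / "mapping.csv", index=False)
    edna_fams = {a.family for a in plant if a.family}
    gbif_fams = set(occ["family"])
    ov = geomapping.overlap_stats(edna_fams, gbif_fams)
    stage("mapping", shared_families=ov.shared, unique_edna=ov.unique_a,
          unique_gbif=ov.unique_b,
          mean_reference_coverage_pct=float(np.nanmean(cov_series)))

    report["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
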