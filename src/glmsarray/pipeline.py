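"""End-to-end pipeline: simulate -> consensus -> normalize -> fit -> mm ->
rescue -> conserve, with file-based stage hand-off and a run manifest.

Every stage reads its inputs from, and writes tidy delimited-text tables to,
a single working directory, so stages can be re-run individually (from the
CLI) or all at once via :func:`run_pipeline`.  One global seed fans out
deterministically to per-stage generators; identical config + seed gives
byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import construct as _construct
from .barcodes import ASSIGNED, BarcodeGroup, assign_clusters, build_consensus_map
from .conservation import (
    correlate_conservation,
    mutation_frequency,
    single_mutant_frequency,
)
from .kinetics import DecayModel, FitBounds
from .mm import fit_michaelis_menten
from .interactions import build_rescue_table, rate_matrix, rescue_matrix
from .normalize import normalize_experiment
from .simulate import (
    LibraryDesign,
    _mutate_read,
    build_ground_truth,
    clusters_to_frame,
    default_schedule,
    ImagingSchedule,
    simulate_clusters,
    simulate_homologs,
    simulate_library,
    simulate_reads,
)
from .variants import Variant

TSV = {"sep": "\t", "index": False, "float_format": "%.10g"}


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run (thresholds at their field defaults)."""

    seed: int = 0
    # --- simulator ---
    doping_fraction: float = 0.013
    deletion_rate: float = 0.002
    double_incorporation_rate: float = 0.002
    bottleneck_size: int = 700_000
    barcode_length: int = 16
    n_tiles: int = 19
    noise_sd: float = 0.02
    n_clusters_per_variant: int = 5
    n_reads_per_barcode: int = 5
    sequencing_error_rate: float = 0.001
    baseline_mean: float = 1000.0
    baseline_cv: float = 0.2
    max_variants: int | None = None
    ensure_reference_variants: bool = True
    concentrations: list[float] = field(
        default_factory=lambda: [0.04, 0.16, 0.64, 2.5, 10.0]
    )
    # --- thresholds ---
    min_match_fraction: float = 0.66
    alpha: float = 0.05
    hamming_max: int = 2
    delta_bic: float = 10.0
    amplitude_min: float = 0.10
    rate_floor: float = 1e-6
    max_bic: float = -200.0
    k_min: float = 1e-7
    k_max: float = 1.0
    # --- conservation ---
    n_homologs: int = 385
    homolog_fasta: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_match_fraction <= 1:
            raise ValueError("min_match_fraction must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.hamming_max < 0 or self.delta_bic < 0:
            raise ValueError("hamming_max and delta_bic must be nonnegative")
        if not 0 <= self.amplitude_min <= 1:
            raise ValueError("amplitude_min must lie in [0, 1]")
        if not 0 < self.k_min < self.k_max:
            raise ValueError("need 0 < k_min < k_max")
        if sorted(self.concentrations) != list(self.concentrations) or min(
            self.concentrations, default=1
        ) <= 0:
            raise ValueError("concentrations must be positive and increasing")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- derived objects ----------------------------------------------------
    def library_design(self) -> LibraryDesign:
        return LibraryDesign(
            doping_fraction=self.doping_fraction,
            deletion_rate=self.deletion_rate,
            double_incorporation_rate=self.double_incorporation_rate,
            bottleneck_size=self.bottleneck_size,
            barcode_length=self.barcode_length,
        )

    def fit_bounds(self) -> FitBounds:
        return FitBounds(k_min=self.k_min, k_max=self.k_max)

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator fanned out from the global seed."""
        stage_key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage_key]))


def _conc_tag(c: float) -> str:
    return f"{c:g}mM"


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    """Generate library, ground truth, cluster tables and sequencing reads."""
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.library_design()
    schedule = default_schedule()
    rng_lib = config.stage_rng("library")
    library = simulate_library(design, rng_lib)
    if config.ensure_reference_variants:
        present = {v.label for v, _ in library}
        median_ab = int(np.median([a for _, a in library])) if library else 1
        for lbl in ("consensus",) + _construct.REFERENCE_NONCLEAVER_LABELS:
            if lbl not in present:
                library.append((Variant.from_label(lbl), max(median_ab, 1)))
    if config.max_variants is not None and len(library) > config.max_variants:
        keep = {"consensus", *_construct.REFERENCE_NONCLEAVER_LABELS}
        ranked = sorted(library, key=lambda kv: (-kv[1], kv[0].label))
        chosen = [kv for kv in ranked if kv[0].label in keep]
        chosen += [kv for kv in ranked if kv[0].label not in keep]
        library = sorted(
            chosen[: config.max_variants], key=lambda kv: kv[0].label
        )
    truth = build_ground_truth(
        [v for v, _ in library],
        schedule,
        config.stage_rng("truth"),
        n_tiles=config.n_tiles,
        noise_sd=config.noise_sd,
    )

    pd.DataFrame(
        {"variant": [v.label for v, _ in library], "abundance": [a for _, a in library]}
    ).to_csv(outdir / "library.tsv", **TSV)
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", **TSV)
    schedule.to_frame().to_csv(outdir / "schedule.tsv", **TSV)
    with open(outdir / "consensus.fasta", "w") as fh:
        fh.write(">consensus_construct\n")
        fh.write(design.consensus_sequence + "\n")

    read_frames = []
    rng_seq = config.stage_rng("sequencing")
    for c in config.concentrations:
        clusters = simulate_clusters(
            library,
            truth,
            c,
            config.n_clusters_per_variant,
            config.stage_rng(f"clusters:{_conc_tag(c)}"),
            design=design,
            baseline_mean=config.baseline_mean,
            baseline_cv=config.baseline_cv,
        )
        df = clusters_to_frame(clusters)
        # the cluster's own sequencing read, with per-base errors
        df["sequence"] = [
            _mutate_read(s, config.sequencing_error_rate, rng_seq)
            for s in df["sequence"]
        ]
        df.to_csv(outdir / f"clusters_{_conc_tag(c)}.tsv", **TSV)
        read_frames.append(
            simulate_reads(
                clusters,
                config.n_reads_per_barcode,
                config.sequencing_error_rate,
                config.stage_rng(f"reads:{_conc_tag(c)}"),
            )
        )
    pd.concat(read_frames, ignore_index=True).to_csv(outdir / "reads.tsv", **TSV)


def _consensus_map_from_table(df: pd.DataFrame) -> dict[str, BarcodeGroup]:
    groups = {}
    for _, row in df.iterrows():
        groups[row["barcode"]] = BarcodeGroup(
            barcode=row["barcode"],
            reads=(),
            modal_sequence=row["consensus"] if isinstance(row["consensus"], str) else "",
            kept=bool(row["kept"]),
            match_fractions=np.empty(0),
            p_values=np.empty(0),
        )
    return groups


def stage_consensus(config: PipelineConfig, outdir: Path) -> None:
    """Call per-barcode consensus sequences and assign clusters to variants."""
    reads = _read_tsv(outdir / "reads.tsv")
    groups, summary = build_consensus_map(
        reads, config.min_match_fraction, config.alpha
    )
    summary.to_csv(outdir / "consensus_map.tsv", **TSV)
    design = config.library_design()
    for c in config.concentrations:
        tag = _conc_tag(c)
        clusters = _read_tsv(outdir / f"clusters_{tag}.tsv")
        assigned = assign_clusters(
            clusters,
            groups,
            design.consensus_sequence,
            design.flank,
            config.hamming_max,
        )
        assigned.to_csv(outdir / f"assigned_{tag}.tsv", **TSV)


def stage_normalize(config: PipelineConfig, outdir: Path) -> None:
    """Baseline- and tile-normalise assigned clusters per concentration."""
    schedule = ImagingSchedule.from_frame(_read_tsv(outdir / "schedule.tsv"))
    for c in config.concentrations:
        tag = _conc_tag(c)
        assigned = _read_tsv(outdir / f"assigned_{tag}.tsv")
        assigned = assigned[assigned["assignment_status"] == ASSIGNED]
        series, discarded = normalize_experiment(assigned, schedule)
        series.to_csv(outdir / f"normalized_{tag}.tsv", **TSV)
        if discarded:
            (outdir / f"discarded_{tag}.txt").write_text("\n".join(discarded) + "\n")


def stage_fit(config: PipelineConfig, outdir: Path) -> None:
    """Fit per-variant decay series at each concentration; BIC-select."""
    bounds = config.fit_bounds()
    rows = []
    for c in config.concentrations:
        tag = _conc_tag(c)
        series = _read_tsv(outdir / f"normalized_{tag}.tsv")
        for variant, sub in series.groupby("variant", sort=True):
            if len(sub) < 4:
                continue
            fit = DecayModel.from_series(sub, bounds).fit(
                delta_bic=config.delta_bic,
                amplitude_min=config.amplitude_min,
                rate_floor=config.rate_floor,
                max_bic=config.max_bic,
            )
            rows.append(
                {
                    "variant": variant,
                    "concentration_mM": c,
                    "model": fit.model,
                    "k_obs_per_s": fit.k_obs,
                    "sigma_k_obs_per_s": fit.sigma_k_obs,
                    "f_fast": fit.amplitude_fraction_fast,
                    "bic_single": fit.bic_single,
                    "bic_double": fit.bic_double,
                    "quality_pass": fit.quality_pass,
                    "below_floor": fit.below_floor,
                    "n_points": fit.n_points,
                    "n_tiles": sub["tile_id"].nunique(),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "kinetic_fits.tsv", **TSV)


def stage_mm(config: PipelineConfig, outdir: Path) -> None:
    """Weighted Michaelis-Menten fits for variants with >= 3 usable rates."""
    fits = _read_tsv(outdir / "kinetic_fits.tsv")
    usable = fits[fits["quality_pass"]]
    rows = []
    for variant, sub in usable.groupby("variant", sort=True):
        sub = sub.sort_values("concentration_mM")
        status = "ok"
        if len(sub) < 3:
            status = "too_few_points"
            rows.append({"variant": variant, "status": status})
            continue
        mmfit = fit_michaelis_menten(
            sub["concentration_mM"], sub["k_obs_per_s"], sub["sigma_k_obs_per_s"]
        )
        if not mmfit.success:
            rows.append({"variant": variant, "status": "fit_failed"})
            continue
        rows.append(
            {
                "variant": variant,
                "status": status,
                "k_cat_per_s": mmfit.k_cat,
                "sigma_k_cat_per_s": mmfit.sigma_k_cat,
                "K_M_mM": mmfit.K_M,
                "sigma_K_M_mM": mmfit.sigma_K_M,
                "efficiency_per_s_per_mM": mmfit.efficiency,
                "accepted_kcat": mmfit.accepted_kcat,
                "accepted_KM": mmfit.accepted_KM,
                "n_points": mmfit.n_points,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "mm_fits.tsv", **TSV)


def stage_rescue(config: PipelineConfig, outdir: Path) -> None:
    """Double-mutant rescue table and heatmap matrices at saturating ligand."""
    fits = _read_tsv(outdir / "kinetic_fits.tsv")
    c_sat = max(config.concentrations)
    sub = fits[(fits["concentration_mM"] == c_sat) & fits["quality_pass"]]
    rates = {
        r["variant"]: (r["k_obs_per_s"], r["sigma_k_obs_per_s"])
        for _, r in sub.iterrows()
    }
    table = build_rescue_table(rates, floor=config.rate_floor)
    table.to_csv(outdir / "rescue_long.tsv", **TSV)
    if not table.empty:
        rescue_matrix(table).to_csv(outdir / "rescue_matrix.tsv", sep="\t",
                                    float_format="%.10g")
        rate_matrix(rates).to_csv(outdir / "rate_matrix.tsv", sep="\t",
                                  float_format="%.10g")


def stage_conserve(config: PipelineConfig, outdir: Path) -> None:
    """Per-base conservation frequencies and kinetics correlations."""
    if config.homolog_fasta:
        from Bio import SeqIO

        homologs = [
            str(rec.seq) for rec in SeqIO.parse(config.homolog_fasta, "fasta")
        ]
    else:
        homologs = simulate_homologs(config.n_homologs, config.stage_rng("homologs"))
        with open(outdir / "homologs.fasta", "w") as fh:
            for i, s in enumerate(homologs):
                fh.write(f">synthetic_homolog_{i}\n{s}\n")
    freq = mutation_frequency(homologs, _construct.CORE_CONSENSUS)
    freq.to_csv(outdir / "conservation.tsv", **TSV)

    fits = _read_tsv(outdir / "kinetic_fits.tsv")
    mm = _read_tsv(outdir / "mm_fits.tsv")
    c_sat = max(config.concentrations)
    kobs = {
        r["variant"]: r["k_obs_per_s"]
        for _, r in fits[
            (fits["concentration_mM"] == c_sat) & fits["quality_pass"]
        ].iterrows()
    }
    params: dict[str, dict[str, float]] = {f"k_obs({c_sat:g} mM)": kobs}
    if "k_cat_per_s" in mm.columns:
        ok = mm[mm["status"] == "ok"]
        params["k_cat"] = {
            r["variant"]: r["k_cat_per_s"]
            for _, r in ok[ok["accepted_kcat"].fillna(False)].iterrows()
        }
        params["K_M"] = {
            r["variant"]: r["K_M_mM"]
            for _, r in ok[ok["accepted_KM"].fillna(False)].iterrows()
        }
        both = ok[ok["accepted_kcat"].fillna(False) & ok["accepted_KM"].fillna(False)]
        params["k_cat/K_M"] = {
            r["variant"]: r["efficiency_per_s_per_mM"] for _, r in both.iterrows()
        }
    # f_mut per single point substitution present in the kinetic tables
    f_mut: dict[str, float] = {}
    all_labels = set().union(*[set(v) for v in params.values()]) if params else set()
    for label in all_labels:
        v = Variant.from_label(label)
        if v.n_mutations != 1 or v.mutations[0].kind != "substitution":
            continue
        if not 1 <= v.mutations[0].position <= len(_construct.CORE_CONSENSUS):
            continue
        try:
            f_mut[label] = single_mutant_frequency(freq, label)
        except KeyError:
            continue
    rows = []
    for name, kin in params.items():
        try:
            res = correlate_conservation(f_mut, kin, parameter=name)
            rows.append(
                {
                    "parameter": name,
                    "spearman_rho": res.rho,
                    "p_two_tailed": res.p_value,
                    "n_pairs": res.n,
                    "status": "ok" if math.isfinite(res.rho) else "undefined",
                }
            )
        except ValueError:
            rows.append(
                {
                    "parameter": name,
                    "spearman_rho": math.nan,
                    "p_two_tailed": math.nan,
                    "n_pairs": 0,
                    "status": "too_few_pairs",
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "correlations.tsv", **TSV)


STAGES = {
    "simulate": stage_simulate,
    "consensus": stage_consensus,
    "normalize": stage_normalize,
    "fit": stage_fit,
    "mm": stage_mm,
    "rescue": stage_rescue,
    "conserve": stage_conserve,
}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages in order and write a run manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for name, fn in STAGES.items():
        try:
            fn(config, outdir)
        except Exception as exc:  # stage-tagged failure
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "glmsarray_version": __version__,
        "stages": list(STAGES),
        "tables": {
            p.name: sum(1 for _ in open(p)) - 1
            for p in sorted(outdir.glob("*.tsv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
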