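"""Forward simulation of an RNA-array self-cleavage experiment.

The simulator produces the three ingredients the analysis pipeline consumes:

1. a doped-synthesis mutant library, bottlenecked to a fixed molecule count
   (:func:`simulate_library`);
2. ground-truth cleavage kinetics for every variant, following the
   Michaelis-Menten law ``k_obs(C) = k_cat C / (K_M + C)`` with rates set by
   a structure-aware effect model (:func:`build_ground_truth`);
3. per-cluster fluorescence decay traces over a two-phase imaging schedule,
   with tile-level multiplicative drift (photobleaching/focus) and additive
   Gaussian noise (:func:`simulate_clusters`), plus sequencing reads with
   per-base errors (:func:`simulate_reads`) and synthetic biological
   homolog sets for the conservation analysis (:func:`simulate_homologs`).

Defaults mirror the experimental design this pipeline targets: a 54-nt doped
region at 1.3% per non-consensus base, bottleneck of ~700,000 molecules,
16-nt random barcodes, five ligand concentrations, and ~14 h of imaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import construct as _construct
from .variants import (
    DELETION,
    INSERTION,
    RNA_BASES,
    SUBSTITUTION,
    Mutation,
    Variant,
    WATSON_CRICK,
    apply_variant,
    canonicalize,
    index_to_pos,
)

#: Saturating cleavage rate of the consensus ribozyme (s^-1), chosen so that
#: k_obs at 10 mM ligand is 6.4e-2 s^-1 with K_M = 2.0 mM.
CONSENSUS_K_CAT = 6.4e-2 * (2.0 + 10.0) / 10.0
CONSENSUS_K_M = 2.0

#: The five assayed ligand concentrations (mM).
DEFAULT_CONCENTRATIONS = (0.04, 0.16, 0.64, 2.5, 10.0)


# ---------------------------------------------------------------------------
# imaging schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagingSchedule:
    """Ordered imaging timepoints in seconds since ligand introduction.

    The first ``n_baseline`` entries are pre-ligand baseline images and sit
    at t = 0; the rest are strictly increasing.
    """

    times: tuple[float, ...]
    n_baseline: int = 2

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) < self.n_baseline + 2:
            raise ValueError("schedule too short")
        if np.any(t[: self.n_baseline] != 0.0):
            raise ValueError("baseline images must sit at t = 0")
        post = t[self.n_baseline :]
        if np.any(np.diff(post) <= 0) or post[0] <= 0:
            raise ValueError("post-ligand timepoints must be strictly increasing")

    @property
    def t_post(self) -> np.ndarray:
        """Seconds since ligand introduction (0 for baseline images)."""
        return np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.times)),
                "time_s": self.times,
                "is_baseline": [i < self.n_baseline for i in range(len(self.times))],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImagingSchedule":
        return cls(tuple(df["time_s"].astype(float)), int(df["is_baseline"].sum()))


def default_schedule(
    dense_interval: float = 10.0,
    dense_until: float = 300.0,
    geometric_factor: float = 1.3,
    total_time: float = 50_400.0,
) -> ImagingSchedule:
    """Two t = 0 baseline images, 10-s sampling for the first 5 min, then
    geometrically spaced imaging out to ~14 h.  Spans rates 1e-1..1e-6 1/s."""
    times = [0.0, 0.0]
    times += list(np.arange(dense_interval, dense_until + 1e-9, dense_interval))
    t = dense_until
    while t < total_time:
        t = min(t * geometric_factor, total_time)
        times.append(round(t, 3))
    return ImagingSchedule(tuple(times))


# ---------------------------------------------------------------------------
# library design and doped-synthesis simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryDesign:
    """Doped-synthesis library parameters.

    ``doping_fraction`` is the mole fraction of EACH of the three
    non-consensus bases per doped position; ``deletion_rate`` and
    ``double_incorporation_rate`` model solid-phase synthesis indels.
    ``doped_region`` is a 0-based half-open interval into
    ``consensus_sequence``; ``excluded_indices`` removes positions inside it
    (e.g. the top half of a hairpin left undoped by design).
    """

    consensus_sequence: str = _construct.FULL_CONSTRUCT
    doped_region: tuple[int, int] = _construct.DOPED_REGION
    doping_fraction: float = 0.013
    deletion_rate: float = 0.002
    double_incorporation_rate: float = 0.002
    bottleneck_size: int = 700_000
    barcode_length: int = 16
    flank: int = _construct.FLANK
    excluded_indices: frozenset[int] = _construct.EXCLUDED_INDICES

    def __post_init__(self) -> None:
        if not 0.0 <= self.doping_fraction <= 1.0 / 3.0:
            raise ValueError("doping_fraction must lie in [0, 1/3]")
        lo, hi = self.doped_region
        if not (0 <= lo < hi <= len(self.consensus_sequence)):
            raise ValueError("doped_region outside sequence bounds")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if min(self.deletion_rate, self.double_incorporation_rate) < 0:
            raise ValueError("indel rates must be nonnegative")
        p = 3 * self.doping_fraction + self.deletion_rate + self.double_incorporation_rate
        if p > 1.0:
            raise ValueError(f"per-position event probabilities sum to {p} > 1")
        if not self.doped_indices():
            raise ValueError("doped region is empty after exclusions")

    def doped_indices(self) -> list[int]:
        lo, hi = self.doped_region
        return [i for i in range(lo, hi) if i not in self.excluded_indices]


def optimal_two_mismatch_doping(n_positions: int = 54) -> float:
    """Per-non-consensus-base doping rate maximising the fraction of
    molecules carrying exactly two mismatches over ``n_positions`` doped
    positions (Binomial argmax: total mutation probability 2/n)."""
    return (2.0 / n_positions) / 3.0


def simulate_library(
    design: LibraryDesign, seed: int | np.random.Generator = 0
) -> list[tuple[Variant, int]]:
    """Draw ``bottleneck_size`` molecules from the doped-synthesis process
    and collapse them to canonical variants with abundances.

    Each doped position independently receives: a substitution to each of
    the three non-consensus bases w.p. ``doping_fraction`` each, a point
    deletion w.p. ``deletion_rate``, or a duplicate incorporation of the
    expected base w.p. ``double_incorporation_rate``.
    """
    rng = np.random.default_rng(seed)
    idx = np.asarray(design.doped_indices(), dtype=np.int64)
    m = len(idx)
    d, dl, ins = (
        design.doping_fraction,
        design.deletion_rate,
        design.double_incorporation_rate,
    )
    # per-position outcome codes: 0..2 substitutions (alphabetical order of
    # the three non-consensus bases), 3 deletion, 4 insertion, 5 consensus
    cum = np.array([d, 2 * d, 3 * d, 3 * d + dl, 3 * d + dl + ins])
    counts: dict[bytes, int] = {}
    n_consensus = 0
    chunk = 131_072
    remaining = design.bottleneck_size
    while remaining > 0:
        n = min(chunk, remaining)
        remaining -= n
        codes = np.searchsorted(cum, rng.random((n, m)), side="right").astype(np.uint8)
        mutated = (codes != 5).any(axis=1)
        n_consensus += int(n - mutated.sum())
        sub = codes[mutated]
        if len(sub):
            rows, row_counts = np.unique(sub, axis=0, return_counts=True)
            for row, c in zip(rows, row_counts):
                key = row.tobytes()
                counts[key] = counts.get(key, 0) + int(c)

    alt_bases = [sorted(set(RNA_BASES) - {design.consensus_sequence[i]}) for i in idx]
    out: dict[Variant, int] = {}
    if n_consensus:
        out[Variant()] = n_consensus
    for key, c in counts.items():
        row = np.frombuffer(key, dtype=np.uint8)
        muts: list[Mutation] = []
        for j in np.nonzero(row != 5)[0]:
            i = int(idx[j])
            pos = index_to_pos(i, design.flank)
            ref = design.consensus_sequence[i]
            code = int(row[j])
            if code < 3:
                muts.append(Mutation(pos, SUBSTITUTION, ref, alt_bases[j][code]))
            elif code == 3:
                muts.append(Mutation(pos, DELETION, ref))
            else:
                muts.append(Mutation(pos, INSERTION, ref))
        v = canonicalize(muts, design.consensus_sequence, design.flank)
        if any(m.is_indel for m in v.mutations):
            # indel genotypes can be sequence-ambiguous (a substitution next
            # to a deletion mimics a shifted deletion); the sequence-based
            # caller is the canonical authority for those
            from .alignment import genotype_from_sequence

            try:
                v = genotype_from_sequence(
                    apply_variant(design.consensus_sequence, v, design.flank),
                    design.consensus_sequence,
                    design.flank,
                )
            except ValueError:
                # rare indel+substitution combinations admit no in-model
                # minimal call; keep the event-based genotype
                pass
        out[v] = out.get(v, 0) + c
    return sorted(out.items(), key=lambda kv: (kv[0].n_mutations, kv[0].label))


# ---------------------------------------------------------------------------
# ground-truth kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticEffectModel:
    """Maps a genotype to a true k_cat via multiplicative per-feature effects.

    With ``independent=True`` every mutation contributes a fixed per-position
    multiplier (no pairing logic), so double-mutant rates are exactly the
    product of single-mutant rate reductions — useful for testing the
    independence expectation.  Otherwise disrupting a designed basepair costs
    ``pair_penalty`` once per pair, and a compensatory double that restores
    Watson-Crick complementarity costs only ``restored_factor``.
    """

    k_cat_consensus: float = CONSENSUS_K_CAT
    pair_penalty: float = 0.02
    restored_factor: float = 0.5
    catalytic_penalty: float = 1e-5
    loop_penalty: float = 0.7
    deletion_penalty: float = 0.05
    insertion_penalty: float = 0.5
    k_cat_floor: float = 1e-8
    independent: bool = False
    duplexes: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(_construct.DUPLEXES)
    )
    catalytic_positions: frozenset[int] = _construct.CATALYTIC_POSITIONS
    core: str = _construct.CORE_CONSENSUS

    def _duplex_positions(self) -> frozenset[int]:
        return frozenset(
            p for pairs in self.duplexes.values() for pq in pairs for p in pq
        )

    def k_cat(self, variant: Variant) -> float:
        k = self.k_cat_consensus
        duplex_pos = self._duplex_positions()
        mutated = {m.position: m for m in variant.mutations}
        for m in variant.mutations:
            if m.position in self.catalytic_positions:
                k *= self.catalytic_penalty
            if m.kind == DELETION:
                k *= self.deletion_penalty
            elif m.kind == INSERTION:
                k *= self.insertion_penalty
        if self.independent:
            for m in variant.mutations:
                if m.kind != SUBSTITUTION:
                    continue
                k *= self.pair_penalty if m.position in duplex_pos else self.loop_penalty
        else:
            seen_pairs = set()
            for name, pairs in self.duplexes.items():
                for p, q in pairs:
                    if p not in mutated and q not in mutated:
                        continue
                    seen_pairs.add((p, q))
                    b5 = self._effective_base(variant, mutated, p)
                    b3 = self._effective_base(variant, mutated, q)
                    if b5 is None or b3 is None or WATSON_CRICK[b5] != b3:
                        k *= self.pair_penalty
                    else:
                        k *= self.restored_factor
            for m in variant.mutations:
                if m.kind != SUBSTITUTION or m.position in duplex_pos:
                    continue
                k *= self.loop_penalty
        return max(k, self.k_cat_floor)

    def _effective_base(
        self, variant: Variant, mutated: Mapping[int, Mutation], pos: int
    ) -> str | None:
        m = mutated.get(pos)
        if m is None:
            return self.core[pos - 1]
        if m.kind == SUBSTITUTION:
            return m.alt
        return None  # an indel at a paired position breaks the pair


@dataclass
class GroundTruth:
    """Generating parameters for a simulated experiment."""

    kinetics: dict[Variant, tuple[float, float]]  # variant -> (k_cat 1/s, K_M mM)
    tile_gains: dict[int, np.ndarray]  # multiplicative gain sampled at schedule
    noise_sd: float  # additive noise sd as fraction of baseline
    schedule: ImagingSchedule

    def __post_init__(self) -> None:
        for v, (kc, km) in self.kinetics.items():
            if kc < 0 or km <= 0:
                raise ValueError(f"bad kinetics for {v.label}: {kc}, {km}")
        for tile, g in self.tile_gains.items():
            g = np.asarray(g, float)
            if len(g) != len(self.schedule) or np.any(g <= 0):
                raise ValueError(f"tile {tile}: gain curve must be positive and "
                                 "match the schedule length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def k_obs(self, variant: Variant, concentration_mm: float) -> float:
        k_cat, km = self.kinetics[variant]
        if concentration_mm == 0:
            return 0.0
        return k_cat * concentration_mm / (km + concentration_mm)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant": v.label, "k_cat_per_s": kc, "K_M_mM": km}
            for v, (kc, km) in sorted(
                self.kinetics.items(), key=lambda kv: kv[0].label
            )
        ]
        return pd.DataFrame(rows)


def bleaching_gain(
    schedule: ImagingSchedule, end_gain: float, curvature: float = 1.0
) -> np.ndarray:
    """Monotone multiplicative gain decaying from 1 to ``end_gain`` over the
    schedule (photobleaching + drift stand-in)."""
    if end_gain <= 0:
        raise ValueError("end_gain must be positive")
    t = schedule.t_post
    total = t[-1] if t[-1] > 0 else 1.0
    return np.exp(math.log(end_gain) * (t / total) ** curvature)


def build_ground_truth(
    variants: Iterable[Variant],
    schedule: ImagingSchedule | None = None,
    seed: int | np.random.Generator = 0,
    *,
    n_tiles: int = 19,
    noise_sd: float = 0.02,
    km_consensus: float = CONSENSUS_K_M,
    km_log_sd: float = 0.2,
    effect_model: KineticEffectModel | None = None,
    end_gain_range: tuple[float, float] = (0.5, 0.9),
    flat_gain: bool = False,
) -> GroundTruth:
    """Assign (k_cat, K_M) to every variant and draw per-tile gain curves.

    K_M scatters lognormally (sd ``km_log_sd`` in log space) around the
    consensus value, independently of k_cat.
    """
    rng = np.random.default_rng(seed)
    schedule = schedule or default_schedule()
    model = effect_model or KineticEffectModel()
    kinetics: dict[Variant, tuple[float, float]] = {}
    for v in variants:
        km = km_consensus if v.is_consensus else float(
            km_consensus * np.exp(rng.normal(0.0, km_log_sd))
        )
        kinetics[v] = (model.k_cat(v), km)
    gains = {}
    for tile in range(n_tiles):
        if flat_gain:
            gains[tile] = np.ones(len(schedule))
        else:
            end = float(rng.uniform(*end_gain_range))
            gains[tile] = bleaching_gain(schedule, end)
    return GroundTruth(kinetics, gains, noise_sd, schedule)


# ---------------------------------------------------------------------------
# cluster traces and reads
# ---------------------------------------------------------------------------


@dataclass
class ClusterTrace:
    """One cluster's raw intensity time series with its provenance."""

    cluster_id: str
    tile_id: int
    barcode: str
    true_sequence: str
    variant: Variant
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


def random_barcode(rng: np.random.Generator, length: int = 16) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length))


def simulate_clusters(
    library: Sequence[tuple[Variant, int]],
    truth: GroundTruth,
    ligand_concentration_mm: float,
    n_clusters_per_variant: int = 5,
    seed: int | np.random.Generator = 0,
    *,
    design: LibraryDesign | None = None,
    baseline_mean: float = 1000.0,
    baseline_cv: float = 0.2,
) -> list[ClusterTrace]:
    """Forward-model cluster fluorescence decay at one ligand concentration.

    intensity(t) = baseline * gain_tile(t) * exp(-k_obs * t_post) + noise,
    with k_obs from the Michaelis-Menten law and t_post = 0 for the two
    baseline images.  Noise is additive Gaussian with sd
    ``truth.noise_sd * baseline``, truncated at zero.
    """
    if ligand_concentration_mm < 0:
        raise ValueError("ligand concentration must be nonnegative")
    if not library:
        raise ValueError("empty library")
    design = design or LibraryDesign()
    rng = np.random.default_rng(seed)
    tiles = sorted(truth.tile_gains)
    t_post = truth.schedule.t_post
    clusters: list[ClusterTrace] = []
    for v, _abundance in library:
        seq = apply_variant(design.consensus_sequence, v, design.flank)
        k_obs = truth.k_obs(v, ligand_concentration_mm)
        decay = np.exp(-k_obs * t_post)
        # clusters spread over tiles round-robin from a random offset: on a
        # real chip every well-represented variant appears on every tile
        offset = int(rng.integers(len(tiles)))
        for c in range(n_clusters_per_variant):
            tile = int(tiles[(offset + c) % len(tiles)])
            baseline = float(
                baseline_mean * max(1.0 + baseline_cv * rng.normal(), 0.05)
            )
            clean = baseline * truth.tile_gains[tile] * decay
            noisy = clean + rng.normal(0.0, truth.noise_sd * baseline, len(t_post))
            clusters.append(
                ClusterTrace(
                    cluster_id=f"{v.label}|{ligand_concentration_mm:g}mM|{c}",
                    tile_id=tile,
                    barcode=random_barcode(rng, design.barcode_length),
                    true_sequence=seq,
                    variant=v,
                    intensities=np.clip(noisy, 0.0, None),
                )
            )
    return clusters


def clusters_to_frame(clusters: Sequence[ClusterTrace]) -> pd.DataFrame:
    """Wide cluster table: id, tile, barcode, sequence, one column per
    timepoint (``I000``, ``I001``, ...)."""
    n_t = len(clusters[0].intensities)
    rows = []
    for c in clusters:
        row = {
            "cluster_id": c.cluster_id,
            "tile_id": c.tile_id,
            "barcode": c.barcode,
            "sequence": c.true_sequence,
            "true_variant": c.variant.label,
        }
        row.update({f"I{j:03d}": c.intensities[j] for j in range(n_t)})
        rows.append(row)
    return pd.DataFrame(rows)


def intensity_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("I") and c[1:].isdigit()]


def _mutate_read(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        arr[i] = rng.choice(sorted(set(RNA_BASES) - {arr[i]}))
    return "".join(arr)


def simulate_reads(
    clusters: Sequence[ClusterTrace],
    n_reads: int = 4,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sequencing reads (barcode, sequence) for each cluster, with iid
    per-base substitution errors at ``error_rate``."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in clusters:
        for _ in range(n_reads):
            rows.append(
                {"barcode": c.barcode, "sequence": _mutate_read(c.true_sequence, error_rate, rng)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic biological homologs
# ---------------------------------------------------------------------------


def simulate_homologs(
    n: int = 385,
    seed: int | np.random.Generator = 0,
    *,
    core: str = _construct.CORE_CONSENSUS,
    effect_model: KineticEffectModel | None = None,
    rate_scale: float = 0.12,
    rate_power: float = 0.35,
    truncation_prob: float = 0.1,
    max_truncation: int = 8,
) -> list[str]:
    """Homolog sequences whose per-base mutation probability is a monotone
    function of the single-mutant k_cat: well-tolerated positions vary,
    catalytically essential ones stay conserved.  A fraction of sequences is
    terminally truncated to emulate partial sequence data."""
    rng = np.random.default_rng(seed)
    model = effect_model or KineticEffectModel()
    k0 = model.k_cat_consensus
    # per (position, alt base) substitution probability
    probs = []
    for pos in range(1, len(core) + 1):
        ref = core[pos - 1]
        alts = sorted(set(RNA_BASES) - {ref})
        p = [
            rate_scale
            * min(1.0, model.k_cat(Variant.from_label(f"{ref}{pos}{a}")) / k0)
            ** rate_power
            for a in alts
        ]
        probs.append((ref, alts, p))
    out = []
    for _ in range(n):
        seq = []
        for ref, alts, p in probs:
            u = rng.random()
            acc = 0.0
            base = ref
            for a, pa in zip(alts, p):
                acc += pa
                if u < acc:
                    base = a
                    break
            seq.append(base)
        s = "".join(seq)
        if rng.random() < truncation_prob:
            cut = int(rng.integers(1, max_truncation + 1))
            s = s[cut:] if rng.random() < 0.5 else s[: len(s) - cut]
        out.append(s)
    return out
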