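"""Seeded generators for a synthetic drought-stress experiment.

Every generator draws from an independent substream derived from one root
seed, so identical (seed, config) pairs give byte-identical output and
adding a generator never perturbs another. Ground truth is always returned
alongside the simulated tables so downstream recovery can be checked
exactly.

What is emulated:

* per-cultivar physiological index time courses with the qualitative trend
  shapes seen under progressive drought (pigment rise-then-fall, monotone
  electrolyte-leakage increase, ...), emitted as *raw* assay measurements
  obtained by inverting the index formulas;
* DESeq2-style DE result tables with planted per-contrast up/down
  fractions;
* expression matrices built from nine tissue-specific cluster archetypes;
* qPCR Ct tables with planted fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import physiology
from .membership import DEFAULT_DIRECTIONS, NEGATIVE

__all__ = [
    "SimulationConfig",
    "TrendSpec",
    "DEFAULT_TRENDS",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_DEG_FRACTIONS",
    "simulate_physiology",
    "simulate_index_matrix",
    "simulate_deg_table",
    "simulate_expression",
    "simulate_ct",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


TREND_SHAPES = (
    "rise_then_fall",
    "monotone_increase",
    "fall_then_rise",
    "fall_rise_fall",
    "rise_fall_plateau",
)


@dataclass(frozen=True)
class TrendSpec:
    """Noiseless shape of one index over the stress time course.

    ``baseline`` is the control (t = 0) level, ``amplitude`` the excursion
    scale; ``noise_sd`` is the SD of Gaussian noise added per replicate on
    the index scale.
    """

    shape: str
    baseline: float
    amplitude: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in TREND_SHAPES:
            raise ConfigurationError(f"unknown trend shape {self.shape!r}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def evaluate(self, timepoints: Sequence[float]) -> np.ndarray:
        """Noiseless index value at each timepoint."""
        t = np.asarray(timepoints, dtype=float)
        span = t.max() - t.min()
        s = (t - t.min()) / span if span > 0 else np.zeros_like(t)
        if self.shape == "rise_then_fall":
            y = np.sin(np.pi * s)
        elif self.shape == "monotone_increase":
            y = s
        elif self.shape == "fall_then_rise":
            y = -np.sin(np.pi * s)
        elif self.shape == "fall_rise_fall":
            y = -np.sin(2.0 * np.pi * s)
        else:  # rise_fall_plateau
            y = np.where(
                s <= 0.3,
                s / 0.3,
                np.where(s <= 0.7, 1.0 - 0.7 * (s - 0.3) / 0.4, 0.3),
            )
        return self.baseline + self.amplitude * y


#: Default trend per index, mirroring the qualitative time courses reported
#: for drought-stressed leaves: pigments rise then fall; electrolyte leakage
#: rises monotonically; SOD dips before recovering in resistant material;
#: MDA accumulates; proline falls, surges, then declines; soluble protein
#: rises, falls and plateaus. Baselines/amplitudes sit in realistic ranges
#: for the respective units.
DEFAULT_TRENDS: Mapping[str, TrendSpec] = {
    "chl": TrendSpec("rise_then_fall", baseline=1.5, amplitude=1.0),
    "rec": TrendSpec("monotone_increase", baseline=15.0, amplitude=55.0),
    "sod": TrendSpec("fall_then_rise", baseline=450.0, amplitude=150.0),
    "mda": TrendSpec("monotone_increase", baseline=0.015, amplitude=0.018),
    "sp": TrendSpec("rise_fall_plateau", baseline=2.0, amplitude=4.0),
    "pro": TrendSpec("fall_rise_fall", baseline=300.0, amplitude=250.0),
}

#: Planted per-contrast (up, down) DEG fractions: the published per-contrast
#: up/down counts divided by a nominal 25,000 tested genes, preserving the
#: study's pattern (leaf response mostly up, rhizome response mostly down,
#: both peaking at 12 h).
DEFAULT_DEG_FRACTIONS: Mapping[tuple, tuple] = {
    ("leaf", 6): (0.1006, 0.0621),
    ("leaf", 12): (0.1295, 0.0862),
    ("leaf", 24): (0.0084, 0.0013),
    ("leaf", 48): (0.0395, 0.0110),
    ("rhizome", 6): (0.0069, 0.0998),
    ("rhizome", 12): (0.0591, 0.6025),
    ("rhizome", 24): (0.0007, 0.2280),
    ("rhizome", 48): (0.0040, 0.5184),
}

#: Sample groups for expression profiles: two tissues x five timepoints.
DEFAULT_SAMPLE_GROUPS = tuple(
    f"{tissue}_{tp}h" for tissue in ("leaf", "rhizome") for tp in (0, 6, 12, 24, 48)
)

#: Nine expression-pattern archetypes on the log2(FPKM+1) scale emulating
#: the tissue-specific cluster shapes of the drought time course: two
#: leaf-specific patterns (high-dip-recover; off-then-on) and seven
#: rhizome-specific temporal patterns.
DEFAULT_ARCHETYPES: tuple = (
    (5, 2, 2, 4, 5, 0, 0, 0, 0, 0),  # leaf: high at 0 h, dip, late recovery
    (0, 0, 0, 0, 0, 2, 4, 6, 3, 2),  # rhizome: induced to 12 h then down
    (0, 0, 0, 0, 0, 6, 3, 2, 4, 5),  # rhizome: high at 0 h, dip, recovery
    (0, 0, 0, 0, 0, 6, 5, 2, 1, 1),  # rhizome: early-high, declines, stays low
    (0, 0, 0, 0, 0, 6, 5, 2, 2, 4),  # rhizome: like C4 but rebounds at 48 h
    (0, 0, 0, 0, 0, 6, 1, 1, 1, 1),  # rhizome: peak at 0 h only
    (0, 0, 0, 0, 0, 1, 3, 6, 4, 2),  # rhizome: slow rise to 12 h peak
    (0, 0, 0, 0, 0, 5, 5, 1, 4, 6),  # rhizome: nadir at 12 h, late rise
    (1, 5, 5, 5, 5, 0, 0, 0, 0, 0),  # leaf: off at 0 h, stably induced
)


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs for all generators.

    Defaults mirror the study design: 10 cultivars sampled on days
    0/6/12/18/24/30 of progressive drought with 3 replicates for the
    physiology arm, and a 2-tissue x {6,12,24,48} h PEG-stress DE design.
    """

    seed: int = 0
    n_cultivars: int = 10
    timepoints: Sequence[float] = (0, 6, 12, 18, 24, 30)
    n_replicates: int = 3
    n_genes: int = 2000
    noise_sd: float = 0.05
    deg_fractions: Mapping[tuple, tuple] = field(
        default_factory=lambda: dict(DEFAULT_DEG_FRACTIONS)
    )
    effect_size_log2fc: float = 3.0
    cluster_archetypes: Sequence[Sequence[float]] = DEFAULT_ARCHETYPES
    planted_best_cultivar: str | None = "cv01"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 1 or self.n_genes < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.effect_size_log2fc <= 0:
            raise ConfigurationError("effect_size_log2fc must be > 0")
        for contrast, (up, down) in self.deg_fractions.items():
            if not (0 <= up <= 1 and 0 <= down <= 1 and up + down <= 1):
                raise ConfigurationError(
                    f"invalid up/down fractions for contrast {contrast}"
                )

    def cultivar_names(self) -> list[str]:
        return [f"cv{i + 1:02d}" for i in range(self.n_cultivars)]


# per-generator substream ids: a new generator appends a new id and leaves
# existing streams untouched
_STREAMS = {"physiology": 0, "index_matrix": 1, "deg": 2, "expression": 3, "ct": 4}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Physiology: raw assay records via formula inversion
# ---------------------------------------------------------------------------

# fixed protocol constants used when inverting the formulas
_PROTOCOL = {
    "chl": {"fresh_weight": 0.1, "extract_volume": 10.0, "dilution": 1.0},
    "rec": {"conductivity_boiled": 1000.0},
    "mda": {"extract_volume": 10.0, "fresh_weight": 0.1, "d450": 0.0, "d600": 0.05},
    "sod": {
        "a_illuminated_control": 1.0,
        "enzyme_aliquot_volume": 0.05,
        "total_extract_volume": 5.0,
        "fresh_weight": 0.2,
    },
    "sp": {"total_extract_volume": 5.0, "sample_volume": 1.0, "fresh_weight": 0.2},
    "pro": {"total_extract_volume": 5.0, "sample_volume": 2.0, "fresh_weight": 0.2},
}


def _invert_chl(target: float, p: dict) -> dict:
    """Absorbances whose pigment formula evaluates back to ``target``.

    Convention: A470 = 0 (no carotenoid signal; the negative raw carotenoid
    term clamps to zero downstream) and the total concentration is split
    3:2 between Chl a and Chl b, which fixes the otherwise under-determined
    two-pigment linear system.
    """
    c_total = target * p["fresh_weight"] * 1000.0 / (p["extract_volume"] * p["dilution"])
    ca, cb = 0.6 * c_total, 0.4 * c_total
    # solve [13.95 -6.88; -7.32 24.96] [A665 A649]' = [Ca Cb]'
    det = 13.95 * 24.96 - (-6.88) * (-7.32)
    a665 = (24.96 * ca + 6.88 * cb) / det
    a649 = (7.32 * ca + 13.95 * cb) / det
    return {"a665": a665, "a649": a649, "a470": 0.0, **{k: p[k] for k in ("fresh_weight", "extract_volume", "dilution")}}


def _invert_rec(target: float, p: dict) -> dict:
    target = min(max(target, 0.0), 100.0)
    return {
        "conductivity_initial": target / 100.0 * p["conductivity_boiled"],
        "conductivity_boiled": p["conductivity_boiled"],
    }


def _invert_mda(target: float, p: dict) -> dict:
    d532 = p["d600"] + (
        target * p["fresh_weight"] * 1000.0 / p["extract_volume"] + 0.56 * p["d450"]
    ) / 6.452
    return {
        "d450": p["d450"],
        "d532": max(d532, 0.0),
        "d600": p["d600"],
        "extract_volume": p["extract_volume"],
        "fresh_weight": p["fresh_weight"],
    }


def _invert_sod(target: float, p: dict) -> dict:
    vol_ratio = p["total_extract_volume"] / p["enzyme_aliquot_volume"]
    inhibition = target * p["fresh_weight"] / vol_ratio * 0.5
    inhibition = min(max(inhibition, 0.0), 1.0)
    return {
        "a_illuminated_control": p["a_illuminated_control"],
        "a_sample": p["a_illuminated_control"] * (1.0 - inhibition),
        "enzyme_aliquot_volume": p["enzyme_aliquot_volume"],
        "total_extract_volume": p["total_extract_volume"],
        "fresh_weight": p["fresh_weight"],
    }


def _invert_sp(target: float, p: dict, curve: physiology.StandardCurve) -> dict:
    c_ug = target * p["sample_volume"] * p["fresh_weight"] * 1000.0 / p["total_extract_volume"]
    a595 = (c_ug - curve.intercept) / curve.slope
    return {
        "a595": max(a595, 0.0),
        "total_extract_volume": p["total_extract_volume"],
        "sample_volume": p["sample_volume"],
        "fresh_weight": p["fresh_weight"],
    }


def _invert_pro(target: float, p: dict, curve: physiology.StandardCurve) -> dict:
    pro_ug = target * p["sample_volume"] * p["fresh_weight"] / p["total_extract_volume"]
    a520 = (pro_ug - curve.intercept) / curve.slope
    return {
        "a520": max(a520, 0.0),
        "total_extract_volume": p["total_extract_volume"],
        "sample_volume": p["sample_volume"],
        "fresh_weight": p["fresh_weight"],
    }


# lower bound per index keeping inverted measurements physical
_INDEX_FLOOR = {"chl": 0.0, "rec": 0.0, "sod": 0.0, "mda": 0.0, "sp": 0.0, "pro": 0.0}


def simulate_physiology(
    config: SimulationConfig,
    trends: Mapping[str, TrendSpec] | None = None,
) -> dict:
    """Raw assay tables per index, plus a ground-truth sidecar.

    Each cultivar gets mild deterministic baseline/amplitude variation so
    cultivars differ; each replicate observation is the cultivar's
    noiseless trend value plus Gaussian noise (TrendSpec.noise_sd if set,
    otherwise ``config.noise_sd`` times the trend amplitude), truncated to
    the physically valid range before inverting the index formula into raw
    measurements.

    Returns ``{"assays": {index: DataFrame}, "truth": DataFrame,
    "curves": {"sp": ..., "pro": ...}}``.
    """
    trends = dict(DEFAULT_TRENDS) if trends is None else dict(trends)
    missing = set(physiology.ASSAY_NAMES) - set(trends)
    if missing:
        raise ConfigurationError(f"missing TrendSpec for indices: {sorted(missing)}")
    rng = _rng(config, "physiology")
    cultivars = config.cultivar_names()
    curves = {"sp": physiology.DEFAULT_BSA_CURVE, "pro": physiology.DEFAULT_PRO_CURVE}

    assays: dict[str, list] = {name: [] for name in trends}
    truth_rows = []
    for name, spec in trends.items():
        inverter = {
            "chl": _invert_chl,
            "rec": _invert_rec,
            "mda": _invert_mda,
            "sod": _invert_sod,
        }.get(name)
        proto = _PROTOCOL[name]
        # per-cultivar multiplicative variation of baseline and amplitude
        base_mult = 1.0 + 0.2 * (rng.random(len(cultivars)) - 0.5)
        amp_mult = 1.0 + 0.4 * (rng.random(len(cultivars)) - 0.5)
        noise_sd = spec.noise_sd if spec.noise_sd > 0 else config.noise_sd * abs(spec.amplitude)
        if config.noise_sd == 0 and spec.noise_sd == 0:
            noise_sd = 0.0
        for ci, cultivar in enumerate(cultivars):
            cv_spec = replace(
                spec,
                baseline=spec.baseline * base_mult[ci],
                amplitude=spec.amplitude * amp_mult[ci],
                noise_sd=0.0,
            )
            clean = cv_spec.evaluate(config.timepoints)
            for ti, day in enumerate(config.timepoints):
                for rep in range(1, config.n_replicates + 1):
                    value = clean[ti] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    value = max(value, _INDEX_FLOOR[name])
                    if name == "rec":
                        value = min(value, 100.0)
                    if name == "sp":
                        fields = _invert_sp(value, proto, curves["sp"])
                    elif name == "pro":
                        fields = _invert_pro(value, proto, curves["pro"])
                    else:
                        fields = inverter(value, proto)
                    assays[name].append(
                        {"cultivar": cultivar, "day": day, "replicate": rep, **fields}
                    )
                    truth_rows.append(
                        {
                            "cultivar": cultivar,
                            "day": day,
                            "replicate": rep,
                            "index": name,
                            "value": value,
                        }
                    )
    return {
        "assays": {name: pd.DataFrame(rows) for name, rows in assays.items()},
        "truth": pd.DataFrame(truth_rows),
        "curves": curves,
    }


# ---------------------------------------------------------------------------
# Index matrix with a planted winner
# ---------------------------------------------------------------------------

# realistic display ranges per index (membership scoring is affine-invariant,
# so these only set the units of the emitted matrix)
_INDEX_RANGES = {
    "Chl": (0.2, 4.0),
    "REC": (10.0, 90.0),
    "SOD": (100.0, 900.0),
    "MDA": (10.0, 35.0),
    "SP": (1.0, 10.0),
    "Pro": (50.0, 900.0),
}


def simulate_index_matrix(config: SimulationConfig) -> dict:
    """Cultivar x index matrix whose planted cultivar sits at the favorable
    extreme of every index (exactly, at zero noise).

    Returns ``{"values": DataFrame, "directions": dict, "planted": str}``.
    """
    if config.n_cultivars < 2:
        raise ConfigurationError("membership evaluation needs >= 2 cultivars")
    planted = config.planted_best_cultivar
    if planted is None:
        raise ConfigurationError("planted_best_cultivar must be named")
    cultivars = config.cultivar_names()
    if planted not in cultivars:
        raise ConfigurationError(f"planted cultivar {planted!r} not among cultivars")
    rng = _rng(config, "index_matrix")
    data = {}
    for index, direction in DEFAULT_DIRECTIONS.items():
        # latent scores in [0, 1]; the planted cultivar gets the favorable
        # extreme, everyone else lands strictly inside (0.1, 0.9)
        latent = 0.1 + 0.8 * rng.random(len(cultivars))
        pi = cultivars.index(planted)
        latent[pi] = 0.0 if direction == NEGATIVE else 1.0
        if config.noise_sd > 0:
            latent = latent + rng.normal(0.0, config.noise_sd, len(cultivars))
        lo, hi = _INDEX_RANGES[index]
        data[index] = lo + (hi - lo) * latent
    values = pd.DataFrame(data, index=cultivars)
    return {"values": values, "directions": dict(DEFAULT_DIRECTIONS), "planted": planted}


# ---------------------------------------------------------------------------
# DE result tables with planted calls
# ---------------------------------------------------------------------------


def simulate_deg_table(config: SimulationConfig) -> dict:
    """DESeq2-style results with planted up/down fractions per contrast.

    Planted DEGs draw |log2FC| strictly beyond 1 with adjusted p strictly
    below 0.05; planted nulls are strictly inside at least one threshold
    (most have |log2FC| <= 1, a fifth have large fold changes but
    non-significant p, exercising the conjunction). Returns
    ``{"table": DataFrame, "truth": DataFrame}``.
    """
    rng = _rng(config, "deg")
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    rows, truth = [], []
    eps = 1e-6
    for (tissue, tp), (up_frac, down_frac) in sorted(config.deg_fractions.items()):
        n_up = int(round(up_frac * config.n_genes))
        n_down = int(round(down_frac * config.n_genes))
        perm = rng.permutation(config.n_genes)
        up_idx = set(perm[:n_up])
        down_idx = set(perm[n_up : n_up + n_down])
        for gi, gene in enumerate(genes):
            if gi in up_idx:
                lfc = rng.uniform(1.0 + 0.25, 1.0 + config.effect_size_log2fc)
                padj = rng.uniform(eps, 0.05 - eps)
                label = "up"
            elif gi in down_idx:
                lfc = -rng.uniform(1.0 + 0.25, 1.0 + config.effect_size_log2fc)
                padj = rng.uniform(eps, 0.05 - eps)
                label = "down"
            else:
                if rng.random() < 0.2:
                    # large fold change but non-significant
                    lfc = rng.uniform(-3.0, 3.0)
                    padj = rng.uniform(0.05 + eps, 1.0 - eps)
                else:
                    lfc = rng.uniform(-0.95, 0.95)
                    padj = rng.uniform(eps, 1.0 - eps)
                label = "none"
            rows.append(
                {
                    "gene_id": gene,
                    "tissue": tissue,
                    "timepoint": tp,
                    "log2_fold_change": lfc,
                    "adjusted_p": padj,
                }
            )
            truth.append(
                {"gene_id": gene, "tissue": tissue, "timepoint": tp, "true_direction": label}
            )
    return {"table": pd.DataFrame(rows), "truth": pd.DataFrame(truth)}


# ---------------------------------------------------------------------------
# Expression matrices from cluster archetypes
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    sample_groups: Sequence[str] = DEFAULT_SAMPLE_GROUPS,
    tissue_mask: Mapping[int, str] | None = None,
) -> dict:
    """Gene profiles = archetype + Gaussian noise, with true labels.

    ``tissue_mask`` optionally zeroes the groups of one tissue per
    archetype index, e.g. ``{3: "leaf"}`` silences the leaf groups of
    archetype 3 (tissue-specific patterns). Returns ``{"matrix":
    DataFrame, "labels": Series}`` with labels in 1..n_archetypes.
    """
    archetypes = [np.asarray(a, dtype=float) for a in config.cluster_archetypes]
    if len(archetypes) < 2:
        raise ConfigurationError("need >= 2 cluster archetypes")
    for i, a in enumerate(archetypes):
        if a.shape != (len(sample_groups),):
            raise ConfigurationError(
                f"archetype {i} has length {a.size}, expected {len(sample_groups)}"
            )
    if tissue_mask:
        for ai, tissue in tissue_mask.items():
            mask = np.array([g.startswith(tissue) for g in sample_groups])
            archetypes[ai] = np.where(mask, 0.0, archetypes[ai])
    rng = _rng(config, "expression")
    labels = rng.integers(0, len(archetypes), size=config.n_genes)
    profiles = np.stack([archetypes[k] for k in labels])
    if config.noise_sd > 0:
        profiles = profiles + rng.normal(0.0, config.noise_sd, profiles.shape)
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    matrix = pd.DataFrame(profiles, index=genes, columns=list(sample_groups))
    return {
        "matrix": matrix,
        "labels": pd.Series(labels + 1, index=genes, name="cluster"),
    }


# ---------------------------------------------------------------------------
# Ct tables with planted fold changes
# ---------------------------------------------------------------------------


def simulate_ct(
    config: SimulationConfig,
    planted_fold_changes: Mapping[str, float],
    base_target_ct: float = 25.0,
    reference_ct: float = 20.0,
) -> dict:
    """Ct table per gene: control sample plus a treated sample whose target
    Ct is shifted by -log2(fold change); the reference gene is constant.

    Replicate Gaussian noise of SD ``config.noise_sd`` cycles is added to
    the target Ct. Returns ``{"table": DataFrame, "truth": DataFrame}``.
    """
    if not planted_fold_changes:
        raise ConfigurationError("no fold changes supplied")
    for gene, fc in planted_fold_changes.items():
        if not (fc > 0 and math.isfinite(fc)):
            raise ConfigurationError(f"fold change for {gene!r} must be positive")
    rng = _rng(config, "ct")
    rows = []
    for gene in sorted(planted_fold_changes):
        fc = planted_fold_changes[gene]
        for group, shift in (("control", 0.0), ("treated", -math.log2(fc))):
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "sample_id": f"{gene}_{group}",
                        "group": group,
                        "target_ct": base_target_ct + shift + noise,
                        "reference_ct": reference_ct,
                        "replicate": rep,
                    }
                )
    truth = pd.DataFrame(
        {"gene": sorted(planted_fold_changes),
         "true_fold_change": [planted_fold_changes[g] for g in sorted(planted_fold_changes)]}
    )
    return {"table": pd.DataFrame(rows), "truth": truth}
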