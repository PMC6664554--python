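"""Synthetic NPX cohort generation.

Emulates the statistical structure of a surgical thoracic-disease plasma
cohort profiled on a 92-protein oncology panel: four disease groups of
144/68/83/48 samples (lung adenocarcinoma, benign lung disease, colorectal
metastasis, typical carcinoid), log2-scale NPX values with independent
Gaussian noise per protein, additive group-specific effects for a handful of
markers, a small number of proteins with values below their limit of
detection, LAC tumor stages, and an inflammatory / non-inflammatory split of
the benign group.

Every cohort is a pure function of its :class:`CohortConfig` (including the
seed): identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .npx_core import GROUPS, STAGES, NPXMatrix, PanelDefinition, SampleMetadata

__all__ = [
    "EffectSpec",
    "CohortConfig",
    "generate_cohort",
    "study_like_config",
    "DEFAULT_GROUP_SIZES",
    "CENSORED_PROTEINS",
]

DEFAULT_GROUP_SIZES: dict[str, int] = {"LAC": 144, "benign": 68, "CRC_met": 83, "carcinoid": 48}

#: LAC stage counts in the emulated cohort (NA = stage unavailable).
DEFAULT_STAGE_COUNTS: dict[str, int] = {
    "IA": 56, "IB": 18, "IIA": 17, "IIB": 14, "IIIA": 33, "IIIB": 3, "IV": 2, "NA": 1,
}

#: Benign diagnoses counted as inflammatory: acute/chronic pneumonia,
#: inflammatory disease, necrotizing granulomatous inflammation → 37 of 68.
DEFAULT_INFLAMMATORY_FRACTION = 37 / 68

#: Panel proteins that realistically dip below the limit of detection.
CENSORED_PROTEINS: tuple[str, ...] = ("S100A4", "CTSV", "MICA/B", "CEACAM5", "MUC16")

#: Named oncology-panel members used by the default panel; remaining slots
#: are filled with generic identifiers.
_NAMED_PANEL: tuple[str, ...] = (
    "CXCL17", "CEACAM5", "VEGFR2", "ERBB3", "WFDC2", "MSLN", "TCL1A",
    "FCRLB", "VEGFR3", "TXLNA", "CYR61", "SCAMP3",
    "S100A4", "CTSV", "MICA/B", "MUC16",
)


@dataclass(frozen=True)
class EffectSpec:
    """An additive NPX shift for one protein in one disease group."""

    protein_id: str
    group: str
    shift: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not np.isfinite(self.shift):
            raise ValueError("effect shift must be finite")


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    ``baseline_mean``/``baseline_sd`` may be scalars (shared by all proteins)
    or per-protein sequences. Effects are additive on the log2 NPX scale.
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_proteins: int = 92
    baseline_mean: float | Sequence[float] = 5.0
    baseline_sd: float | Sequence[float] = 1.0
    effects: tuple[EffectSpec, ...] = ()
    n_lod_censored_proteins: int = 5
    lod_quantile: float = 0.005
    stage_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_STAGE_COUNTS))
    inflammatory_fraction: float = DEFAULT_INFLAMMATORY_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in group_sizes")
            if n <= 0:
                raise ValueError(f"group size for {g} must be positive")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not 0 <= self.inflammatory_fraction <= 1:
            raise ValueError("inflammatory_fraction must be in [0, 1]")
        if not 0 < self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in (0, 1)")
        if not 0 <= self.n_lod_censored_proteins <= self.n_proteins:
            raise ValueError("n_lod_censored_proteins out of range")
        self.effects = tuple(self.effects)
        unknown = set(self.stage_counts) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def protein_ids(self) -> tuple[str, ...]:
        named = [p for p in _NAMED_PANEL][: self.n_proteins]
        fillers = [f"PROT{k:03d}" for k in range(1, self.n_proteins - len(named) + 1)]
        return tuple(named + fillers)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["effects"] = [asdict(e) for e in self.effects]
        data["group_sizes"] = dict(self.group_sizes)
        data["stage_counts"] = dict(self.stage_counts)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["effects"] = tuple(EffectSpec(**e) for e in data.get("effects", ()))
        return cls(**data)


def study_like_config(seed: int = 0) -> CohortConfig:
    """Default cohort with the marker structure of the emulated study.

    LAC carries elevated CXCL17 and CEACAM5 and reduced VEGFR2 and ERBB3
    relative to baseline; colorectal metastases carry elevated WFDC2 and MSLN,
    so that all five of WFDC2, MSLN, CXCL17, CEACAM5 and VEGFR2 separate
    CRC_met from LAC. The ±0.9 NPX shift (at unit noise SD) was chosen so a
    pooled-median single-marker cut-off classifier lands near the published
    sensitivity/specificity of the strongest single markers, while a 144-vs-68
    rank-sum comparison has near-unit power after FDR adjustment.
    """
    effects = (
        EffectSpec("CXCL17", "LAC", +0.9),
        EffectSpec("CEACAM5", "LAC", +0.9),
        EffectSpec("VEGFR2", "LAC", -0.9),
        EffectSpec("ERBB3", "LAC", -0.9),
        EffectSpec("WFDC2", "CRC_met", +0.9),
        EffectSpec("MSLN", "CRC_met", +0.9),
    )
    return CohortConfig(effects=effects, seed=seed)


def _draw_categorical(rng: np.random.Generator, n: int, labels, probs) -> np.ndarray:
    counts = rng.multinomial(n, np.asarray(probs, dtype=float) / np.sum(probs))
    out = np.repeat(np.asarray(labels, dtype=object), counts)
    rng.shuffle(out)
    return out


def generate_cohort(config: CohortConfig):
    """Simulate a cohort; returns ``(matrix, metadata, panel, truth)``.

    ``truth`` is a DataFrame with columns ``protein_id, group, shift``
    recording every injected effect. NPX values are drawn as
    ``Normal(baseline_mean_j + shift, baseline_sd_j)`` independently per
    protein; LODs are placed at the ``lod_quantile`` of each censored
    protein's simulated values (which guarantees at least one flagged sample)
    and at ``-inf`` for every other protein.
    """
    proteins = config.protein_ids()
    for eff in config.effects:
        if eff.protein_id not in proteins:
            raise ValueError(f"effect references unknown protein {eff.protein_id!r}")

    groups_in_order = [g for g in GROUPS if g in config.group_sizes]
    sizes = [int(config.group_sizes[g]) for g in groups_in_order]
    n_total = int(np.sum(sizes))
    p = config.n_proteins

    mean = np.broadcast_to(np.asarray(config.baseline_mean, dtype=float), (p,)).copy()
    sd = np.broadcast_to(np.asarray(config.baseline_sd, dtype=float), (p,)).copy()
    if np.any(sd <= 0):
        raise ValueError("baseline_sd must be positive")

    rng = np.random.default_rng(config.seed)

    # -- NPX values (one block draw, fixed order) --------------------------
    group_col = np.repeat(groups_in_order, sizes)
    shift_grid = np.zeros((n_total, p))
    col_index = {pid: j for j, pid in enumerate(proteins)}
    for eff in config.effects:
        shift_grid[group_col == eff.group, col_index[eff.protein_id]] += eff.shift
    values = rng.normal(loc=mean[np.newaxis, :] + shift_grid, scale=sd[np.newaxis, :])

    # -- LOD placement ------------------------------------------------------
    lod = {pid: float("-inf") for pid in proteins}
    censored = [pid for pid in CENSORED_PROTEINS if pid in proteins]
    extra = [pid for pid in proteins if pid not in censored]
    censored = (censored + extra)[: config.n_lod_censored_proteins]
    for pid in censored:
        lod[pid] = float(np.quantile(values[:, col_index[pid]], config.lod_quantile))
    panel = PanelDefinition(proteins, lod)

    sample_ids = []
    for g, n in zip(groups_in_order, sizes):
        sample_ids.extend(f"{g}_{i:03d}" for i in range(1, n + 1))
    matrix = NPXMatrix.from_values(tuple(sample_ids), proteins, values, panel)

    # -- metadata (draws in fixed order: stage, inflammatory, sex, age, smoking)
    meta = pd.DataFrame({"sample_id": sample_ids, "group": group_col})
    meta["stage"] = pd.NA
    meta["inflammatory"] = pd.NA
    if "LAC" in groups_in_order:
        n_lac = config.group_sizes["LAC"]
        stage_labels = list(config.stage_counts)
        stage_probs = [config.stage_counts[s] for s in stage_labels]
        meta.loc[meta["group"] == "LAC", "stage"] = _draw_categorical(
            rng, n_lac, stage_labels, stage_probs
        )
    if "benign" in groups_in_order:
        n_ben = config.group_sizes["benign"]
        n_inflam = int(round(config.inflammatory_fraction * n_ben))
        flags = np.array([True] * n_inflam + [False] * (n_ben - n_inflam), dtype=object)
        rng.shuffle(flags)
        meta.loc[meta["group"] == "benign", "inflammatory"] = flags
    # Demographics: group-wise female / age>70 / smoker fractions of the
    # emulated cohort (not used by any downstream statistic).
    demo = {
        "LAC": (81 / 144, 53 / 144, 130 / 144),
        "benign": (34 / 68, 16 / 68, 41 / 68),
        "CRC_met": (41 / 83, 24 / 83, 43 / 83),
        "carcinoid": (31 / 48, 5 / 48, 22 / 48),
    }
    sex = np.empty(n_total, dtype=object)
    age = np.empty(n_total, dtype=object)
    smoker = np.empty(n_total, dtype=object)
    for g in groups_in_order:
        m = group_col == g
        f_female, f_old, f_smoke = demo[g]
        n_g = int(m.sum())
        sex[m] = np.where(rng.random(n_g) < f_female, "F", "M")
        age[m] = np.where(rng.random(n_g) < f_old, "yes", "no")
        smoker[m] = np.where(rng.random(n_g) < f_smoke, "smoker", "non-smoker")
    meta["sex"] = sex
    meta["age_gt_70"] = age
    meta["smoker"] = smoker
    metadata = SampleMetadata(meta)

    truth = pd.DataFrame(
        [(e.protein_id, e.group, e.shift) for e in config.effects],
        columns=["protein_id", "group", "shift"],
    )
    return matrix, metadata, panel, truth
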