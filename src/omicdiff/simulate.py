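"""Synthetic PTM and metabolomics experiments with known ground truth.

The PTM generator draws log-normal protein baselines, assigns each
protein a fixed number of modification sites with site-specific
occupancies, and builds per-cell intensities as

    intensity = protein abundance x occupancy x group effect x noise

with independent multiplicative log-normal noise per cell and optional
missing-at-random masking.  Selected sites receive a fold-change
effect in the perturbed group; with ``coupled_protein_effect`` the
host protein carries the effect and the site tracks it (the scenario
where a site-level decrease drags down total protein), so protein
normalization cancels the site's apparent change.  TMT ratio
compression is modeled as exponent shrinkage: the realized fold is
``fold ** (1 - tmt_compression)``.

The metabolite generator builds class-structured peak-area matrices
for a two- or three-group design (control / stress / rescue): classes
listed in ``group_effects`` scale their members in the named groups,
and a configurable fraction of affected metabolites is returned to the
control level in the rescue group (the reversal the rescue analysis
should detect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .io import MetaboliteTable, SampleSheet, SITE_INDEX

__all__ = [
    "PtmSimConfig",
    "MetabSimConfig",
    "SimTruth",
    "simulate_ptm_experiment",
    "simulate_metabolite_experiment",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20221124

CONTROL_GROUP = "control"
STRESS_GROUP = "CS"
RESCUE_GROUP = "CS_THP"


@dataclass(frozen=True)
class PtmSimConfig:
    """Study conditions for the synthetic PTM experiment.

    Log-scale parameters are natural-log means/SDs of the log-normal
    draws.  ``noise_log_sd`` is the SD of the per-cell multiplicative
    replicate noise; ``tmt_compression`` in [0, 1] shrinks injected
    folds to ``fold ** (1 - compression)``.
    """

    n_proteins: int = 200
    sites_per_protein: int = 2
    n_replicates_per_group: int = 2
    baseline_log_mean: float = 20.0
    baseline_log_sd: float = 1.0
    occupancy_mean: float = 0.3
    noise_log_sd: float = 0.15
    missing_rate: float = 0.0
    n_true_up: int = 10
    n_true_down: int = 10
    effect_fold: float = 2.0
    coupled_protein_effect: bool = False
    tmt_compression: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.sites_per_protein < 1:
            raise ConfigurationError("n_proteins and sites_per_protein must be >= 1")
        if self.n_replicates_per_group < 2:
            raise ConfigurationError("n_replicates_per_group must be >= 2")
        if not (0 < self.occupancy_mean < 1):
            raise ConfigurationError("occupancy_mean must be in (0, 1)")
        if self.noise_log_sd < 0:
            raise ConfigurationError("noise_log_sd must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0 <= self.tmt_compression <= 1):
            raise ConfigurationError("tmt_compression must be in [0, 1]")
        if self.effect_fold <= 1:
            raise ConfigurationError("effect_fold must be > 1")
        n_sites = self.n_proteins * self.sites_per_protein
        if self.n_true_up + self.n_true_down > n_sites:
            raise ConfigurationError("n_true_up + n_true_down exceeds the number of sites")
        if self.n_true_up < 0 or self.n_true_down < 0:
            raise ConfigurationError("n_true_up and n_true_down must be >= 0")

    @property
    def realized_fold(self) -> float:
        """Injected fold after TMT compression, ``fold**(1-compression)``."""
        return float(self.effect_fold ** (1.0 - self.tmt_compression))


@dataclass(frozen=True)
class MetabSimConfig:
    """Study conditions for the synthetic metabolite experiment.

    ``class_spec`` lists (lipid class, member count); ``group_effects``
    maps a class to per-group multiplicative effects relative to
    control (e.g. ``{"PC": {"CS": 0.5}}``).  When ``rescue_fraction``
    is not None a third group is generated and that share of affected
    metabolites has its effect removed there (returned to the control
    mean).
    """

    class_spec: tuple[tuple[str, int], ...] = (
        ("PC", 12), ("PE", 10), ("PI", 4), ("LPC", 6), ("LPE", 5),
        ("LPA", 3), ("PA", 4), ("TG", 14), ("SM", 6), ("other", 16),
    )
    n_per_group: int = 6
    group_effects: dict = field(default_factory=dict)
    baseline_log_mean: float = 13.0
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.15
    rescue_fraction: float | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ConfigurationError("n_per_group must be >= 3")
        if any(count < 1 for _, count in self.class_spec):
            raise ConfigurationError("class counts must be positive")
        if self.noise_log_sd < 0:
            raise ConfigurationError("noise_log_sd must be >= 0")
        if self.rescue_fraction is not None and not (0 <= self.rescue_fraction <= 1):
            raise ConfigurationError("rescue_fraction must be in [0, 1]")
        for cls, effects in self.group_effects.items():
            if isinstance(effects, dict):
                vals = effects.values()
            else:
                raise ConfigurationError(
                    f"group_effects[{cls!r}] must map group -> effect"
                )
            if any(v <= 0 for v in vals):
                raise ConfigurationError("group effects must be positive")


@dataclass
class SimTruth:
    """Ground truth of the injected effects."""

    true_up: set = field(default_factory=set)
    true_down: set = field(default_factory=set)
    true_recovered: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.true_up & self.true_down:
            raise ConfigurationError("true_up and true_down must be disjoint")


def _sample_sheet(groups: list[str], n_per_group: int) -> SampleSheet:
    rows = [
        {"sample_id": f"{grp}_{r}", "group": grp, "replicate_index": r}
        for grp in groups
        for r in range(1, n_per_group + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


def simulate_ptm_experiment(
    cfg: PtmSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SampleSheet, SimTruth]:
    """Generate (site table, protein table, sample sheet, truth).

    Deterministic given ``cfg.seed``.  Group labels are ``control``
    and ``CS``; truth sets contain the site-key tuples whose realized
    CS/control fold is ``cfg.realized_fold`` (up) or its inverse
    (down).
    """
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_proteins * cfg.sites_per_protein
    protein_ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    site_protein = np.repeat(np.arange(cfg.n_proteins), cfg.sites_per_protein)
    positions = np.tile(np.arange(1, cfg.sites_per_protein + 1) * 25 + 1, cfg.n_proteins)
    site_keys = [
        (protein_ids[site_protein[s]], "K", int(positions[s]), "crotonyl")
        for s in range(n_sites)
    ]

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_proteins)
    # occupancy per site: Beta with mean occupancy_mean, concentration 10
    conc = 10.0
    occupancy = rng.beta(cfg.occupancy_mean * conc, (1 - cfg.occupancy_mean) * conc, n_sites)
    occupancy = np.clip(occupancy, 1e-6, 1 - 1e-6)

    chosen = rng.choice(n_sites, size=cfg.n_true_up + cfg.n_true_down, replace=False)
    up_idx = chosen[: cfg.n_true_up]
    down_idx = chosen[cfg.n_true_up:]
    fold = cfg.realized_fold
    site_effect = np.ones(n_sites)
    site_effect[up_idx] = fold
    site_effect[down_idx] = 1.0 / fold

    protein_effect = np.ones(cfg.n_proteins)
    if cfg.coupled_protein_effect:
        # the host protein carries the fold; the site tracks the protein
        for s in chosen:
            protein_effect[site_protein[s]] *= site_effect[s]
        effective_site_extra = np.ones(n_sites)
    else:
        effective_site_extra = site_effect

    sheet = _sample_sheet([CONTROL_GROUP, STRESS_GROUP], cfg.n_replicates_per_group)
    sample_ids = sheet.sample_ids
    is_stress = np.array([sheet.frame.loc[i, "group"] == STRESS_GROUP
                          for i in range(len(sample_ids))])

    n_samples = len(sample_ids)
    prot_expected = baseline[:, None] * np.where(is_stress[None, :],
                                                 protein_effect[:, None], 1.0)
    prot_noise = np.exp(rng.normal(0.0, cfg.noise_log_sd, (cfg.n_proteins, n_samples)))
    prot_values = prot_expected * prot_noise

    site_base = prot_expected[site_protein, :] * occupancy[:, None]
    site_expected = site_base * np.where(is_stress[None, :],
                                         effective_site_extra[:, None], 1.0)
    site_noise = np.exp(rng.normal(0.0, cfg.noise_log_sd, (n_sites, n_samples)))
    site_values = site_expected * site_noise
    if cfg.missing_rate > 0:
        mask = rng.random((n_sites, n_samples)) < cfg.missing_rate
        site_values = np.where(mask, np.nan, site_values)

    index = pd.MultiIndex.from_tuples(site_keys, names=SITE_INDEX)
    sites = pd.DataFrame(site_values, index=index, columns=sample_ids)
    proteins = pd.DataFrame(prot_values, index=pd.Index(protein_ids, name="protein_id"),
                            columns=sample_ids)
    truth = SimTruth(
        true_up={site_keys[s] for s in up_idx},
        true_down={site_keys[s] for s in down_idx},
    )
    return sites, proteins, sheet, truth


def simulate_metabolite_experiment(
    cfg: MetabSimConfig,
) -> tuple[MetaboliteTable, SampleSheet, SimTruth]:
    """Generate (metabolite table, sample sheet, truth).

    Groups are ``control`` and ``CS``, plus ``CS_THP`` when
    ``rescue_fraction`` is set.  A metabolite is true-up/true-down
    according to its class effect in the stress group; rescued
    metabolites have that effect removed in the rescue group.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = [CONTROL_GROUP, STRESS_GROUP]
    three_group = cfg.rescue_fraction is not None
    if three_group:
        groups.append(RESCUE_GROUP)
    sheet = _sample_sheet(groups, cfg.n_per_group)
    sample_ids = sheet.sample_ids
    sample_groups = list(sheet.frame["group"])

    ids, names, classes = [], [], []
    for cls, count in cfg.class_spec:
        for i in range(1, count + 1):
            ids.append(f"{cls}_{i:03d}")
            names.append(f"{cls}({14 + i}:0/18:{i % 3})" if cls != "other" else f"metab_{i:03d}")
            classes.append(cls)
    n_metab = len(ids)

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_metab)
    effect_by_group = {grp: np.ones(n_metab) for grp in groups}
    affected = np.zeros(n_metab, dtype=bool)
    stress_effect = np.ones(n_metab)
    for m, cls in enumerate(classes):
        per_group = cfg.group_effects.get(cls, {})
        for grp, eff in per_group.items():
            if grp not in effect_by_group:
                raise ConfigurationError(f"group_effects references unknown group {grp!r}")
            effect_by_group[grp][m] = eff
        if per_group.get(STRESS_GROUP, 1.0) != 1.0:
            affected[m] = True
            stress_effect[m] = per_group[STRESS_GROUP]

    rescued = np.zeros(n_metab, dtype=bool)
    if three_group:
        # rescue group inherits the stress effect unless explicitly set
        for m in range(n_metab):
            if RESCUE_GROUP not in cfg.group_effects.get(classes[m], {}):
                effect_by_group[RESCUE_GROUP][m] = stress_effect[m]
        affected_idx = np.flatnonzero(affected)
        n_rescued = int(round(cfg.rescue_fraction * len(affected_idx)))
        pick = rng.choice(affected_idx, size=n_rescued, replace=False) if n_rescued else []
        for m in pick:
            rescued[m] = True
            effect_by_group[RESCUE_GROUP][m] = 1.0   # returned to control mean

    effects = np.column_stack([effect_by_group[g] for g in sample_groups])
    noise = np.exp(rng.normal(0.0, cfg.noise_log_sd, (n_metab, len(sample_ids))))
    values = baseline[:, None] * effects * noise

    table = MetaboliteTable(
        values=pd.DataFrame(values, index=pd.Index(ids, name="metabolite_id"),
                            columns=sample_ids),
        names=pd.Series(names, index=ids, name="name"),
        classes=pd.Series(classes, index=ids, name="lipid_class"),
    )
    truth = SimTruth(
        true_up={ids[m] for m in range(n_metab) if affected[m] and stress_effect[m] > 1},
        true_down={ids[m] for m in range(n_metab) if affected[m] and stress_effect[m] < 1},
        true_recovered={ids[m] for m in range(n_metab) if rescued[m]},
    )
    return table, sheet, truth
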