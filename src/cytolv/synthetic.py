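"""Synthetic cytokine panels with known ground truth.

Generates log-normal sample-by-analyte concentration matrices with additive
group effects, an extra cooperative interaction effect in a designated
combined-pathology group, correlated analyte noise, detection-limit
censoring, and continuous phenotypes coupled to the injected inflammation
factor.  Every pipeline stage can therefore be tested for parameter
recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import CytokinePanel, PhenotypeTable, Units

__all__ = [
    "DEFAULT_ANALYTES",
    "SyntheticTruth",
    "generate_panel",
    "preset_scenarios",
]

# 23-plex mouse panel names; G-CSF is appended by presets that exercise
# detection-limit filtering
DEFAULT_ANALYTES = [
    "Eotaxin", "GM-CSF", "IFN-g", "IL-1a", "IL-1b", "IL-2", "IL-3", "IL-4",
    "IL-5", "IL-6", "IL-9", "IL-10", "IL-12p40", "IL-12p70", "IL-13",
    "IL-17", "KC", "MCP-1", "MIP-1a", "MIP-1b", "RANTES", "TNF-a",
]

#: analytes given chemokine-skewed cooperative effects in the presets
CHEMOKINE_SET = ["MIP-1a", "MIP-1b", "MCP-1", "KC", "GM-CSF"]
PROINFLAMMATORY_SET = ["IL-1a", "IFN-g", "IL-3", "IL-17", "IL-1b", "TNF-a"]


@dataclass
class SyntheticTruth:
    """Ground-truth parameterization of a synthetic panel."""

    analytes: list[str]
    groups: list[str]
    combined_group: str | None
    baseline_log_mean: np.ndarray
    log_sd: np.ndarray
    group_effects: dict[str, np.ndarray]
    interaction_effects: np.ndarray
    noise_correlation: np.ndarray
    lod: np.ndarray | None
    phenotype_coupling: dict[str, tuple[float, float, float]]
    group_sizes: dict[str, int]
    seed: int = 0

    def __post_init__(self):
        p = len(self.analytes)
        self.baseline_log_mean = np.asarray(self.baseline_log_mean, float)
        self.log_sd = np.asarray(self.log_sd, float)
        self.interaction_effects = np.asarray(self.interaction_effects, float)
        self.noise_correlation = np.asarray(self.noise_correlation, float)
        for name, arr in (
            ("baseline_log_mean", self.baseline_log_mean),
            ("log_sd", self.log_sd),
            ("interaction_effects", self.interaction_effects),
        ):
            if arr.shape != (p,):
                raise ValueError(f"{name} must have one entry per analyte")
        if (self.log_sd <= 0).any():
            raise ValueError("log_sd must be positive")
        self.group_effects = {
            g: np.asarray(e, float) for g, e in self.group_effects.items()
        }
        for g in self.groups:
            if g not in self.group_effects:
                self.group_effects[g] = np.zeros(p)
            if self.group_effects[g].shape != (p,):
                raise ValueError(f"group_effects[{g!r}] has wrong length")
        if self.noise_correlation.shape != (p, p):
            raise ValueError("noise_correlation must be analyte-by-analyte")
        if not np.allclose(self.noise_correlation, self.noise_correlation.T):
            raise ValueError("noise_correlation must be symmetric")
        if not np.allclose(np.diag(self.noise_correlation), 1.0):
            raise ValueError("noise_correlation must have unit diagonal")
        if self.lod is not None:
            self.lod = np.asarray(self.lod, float)
            if self.lod.shape != (p,):
                raise ValueError("lod must have one entry per analyte")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 2")
        if self.combined_group is not None and self.combined_group not in self.groups:
            raise ValueError(f"combined_group {self.combined_group!r} not in groups")

    def total_effect(self, group: str) -> np.ndarray:
        """Injected log-scale shift for one group (main + interaction)."""
        e = self.group_effects[group].copy()
        if group == self.combined_group:
            e += self.interaction_effects
        return e

    @property
    def affected_analytes(self) -> np.ndarray:
        """Boolean mask of analytes with a nonzero injected effect anywhere."""
        mask = self.interaction_effects != 0
        for g in self.groups:
            mask |= self.group_effects[g] != 0
        return mask

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("baseline_log_mean", "log_sd", "interaction_effects", "lod"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        d["noise_correlation"] = self.noise_correlation.tolist()
        d["group_effects"] = {g: e.tolist() for g, e in self.group_effects.items()}
        d["phenotype_coupling"] = {
            k: list(v) for k, v in self.phenotype_coupling.items()
        }
        return json.dumps(d, indent=2)


def generate_panel(
    truth: SyntheticTruth, seed: int | None = None
) -> tuple[CytokinePanel, PhenotypeTable, SyntheticTruth]:
    """Draw one synthetic panel + phenotype table from a truth object.

    Per sample, log-concentration = baseline + group effect (+ interaction in
    the combined group) + correlated Gaussian noise; concentrations are the
    exponentials, and cells below the analyte's detection limit are flagged
    censored.  Each phenotype is ``intercept + slope * factor + noise`` where
    the sample's inflammation factor is the mean injected log shift across
    affected analytes (zero when no analyte is affected).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    p = len(truth.analytes)
    try:
        L = np.linalg.cholesky(truth.noise_correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise_correlation is not positive-definite") from exc

    rows, sample_ids, group_labels, sex_labels = [], [], [], []
    factors = []
    affected = truth.affected_analytes
    counter = 0
    for g in truth.groups:
        shift = truth.total_effect(g)
        factor = float(shift[affected].mean()) if affected.any() else 0.0
        for _ in range(truth.group_sizes[g]):
            counter += 1
            z = L @ rng.standard_normal(p)
            logc = truth.baseline_log_mean + shift + truth.log_sd * z
            rows.append(np.exp(logc))
            sample_ids.append(f"s{counter:03d}")
            group_labels.append(g)
            sex_labels.append("M" if counter % 2 else "F")
            factors.append(factor)

    values = pd.DataFrame(
        np.array(rows), index=pd.Index(sample_ids, name="sample_id"),
        columns=truth.analytes,
    )
    panel = CytokinePanel(
        values=values,
        group=pd.Series(group_labels, index=values.index, name="group"),
        units=Units.PG_PER_MG,
        sex=pd.Series(sex_labels, index=values.index, name="sex"),
        lod=None if truth.lod is None else pd.Series(truth.lod, index=truth.analytes),
    )

    factors = np.asarray(factors)
    pheno = {}
    for name, (intercept, slope, noise_sd) in truth.phenotype_coupling.items():
        pheno[name] = intercept + slope * factors + noise_sd * rng.standard_normal(
            len(factors)
        )
    phenotypes = PhenotypeTable(pd.DataFrame(pheno, index=values.index))
    return panel, phenotypes, truth


def _exchangeable_corr(p: int, rho: float) -> np.ndarray:
    return np.full((p, p), rho) + (1 - rho) * np.eye(p)


def _effects(analytes: list[str], spec: dict[str, float]) -> np.ndarray:
    e = np.zeros(len(analytes))
    for name, val in spec.items():
        e[analytes.index(name)] = val
    return e


def preset_scenarios(name: str, seed: int = 0) -> SyntheticTruth:
    """Documented scenario parameterizations.

    ``null`` — three groups, no effects (calibration runs).
    ``stz_like`` — amyloid + chemically induced T1D; cooperative
    chemokine/pro-inflammatory interaction in the combined group, high
    glucose / low insulin coupling.
    ``dbdb_like`` — amyloid x genetic T2D; chemokine-skewed interaction,
    glucose positively and insulin negatively coupled to inflammation,
    plasma amyloid negatively coupled.
    ``hfd_like`` — amyloid + diet-induced prediabetes; milder interaction,
    high insulin coupling.

    All presets carry a G-CSF column whose detection limit sits far above
    its typical concentration, exercising the detectability filter.
    """
    analytes = DEFAULT_ANALYTES + ["G-CSF"]
    p = len(analytes)
    baseline = np.linspace(1.5, 4.5, p)
    log_sd = np.full(p, 0.5)
    corr = _exchangeable_corr(p, 0.3)
    # G-CSF sits below its detection limit for most samples
    lod = np.exp(baseline - 2.5)
    lod[analytes.index("G-CSF")] = np.exp(baseline[analytes.index("G-CSF")] + 1.0)

    chemo = {a: 1.2 for a in CHEMOKINE_SET}
    proinfl = {a: 0.8 for a in PROINFLAMMATORY_SET}

    if name == "null":
        groups = ["APP_PS1", "STZ", "APP_PS1-STZ"]
        return SyntheticTruth(
            analytes=analytes,
            groups=groups,
            combined_group="APP_PS1-STZ",
            baseline_log_mean=baseline,
            log_sd=log_sd,
            group_effects={},
            interaction_effects=np.zeros(p),
            noise_correlation=corr,
            lod=lod,
            phenotype_coupling={
                "glucose": (140.0, 40.0, 15.0),
                "insulin": (2.5, -0.8, 0.4),
            },
            group_sizes={g: 7 for g in groups},
            seed=seed,
        )
    if name == "stz_like":
        groups = ["APP_PS1", "STZ", "APP_PS1-STZ"]
        diabetic = "STZ"
        interaction = _effects(analytes, {**chemo, **proinfl})
        pheno = {
            "glucose": (180.0, 60.0, 20.0),
            "insulin": (1.5, -0.6, 0.15),
        }
    elif name == "dbdb_like":
        groups = ["APP_PS1", "db_db", "APP_PS1xdb_db"]
        diabetic = "db_db"
        interaction = _effects(analytes, {**chemo, **{k: 0.5 for k in proinfl}})
        pheno = {
            "glucose": (200.0, 80.0, 25.0),
            "insulin": (4.0, -1.2, 0.3),
            "abeta40": (120.0, -30.0, 10.0),
            "abeta42": (60.0, -15.0, 5.0),
        }
    elif name == "hfd_like":
        groups = ["APP_PS1", "HFD", "APP_PS1-HFD"]
        diabetic = "HFD"
        interaction = _effects(analytes, {**{k: 0.8 for k in chemo},
                                          **{k: 0.4 for k in proinfl}})
        pheno = {
            "glucose": (150.0, 30.0, 15.0),
            "insulin": (3.5, 1.0, 0.4),
        }
    else:
        raise ValueError(f"unknown scenario {name!r}")

    combined = groups[-1]
    group_effects = {
        diabetic: _effects(analytes, {k: 0.4 for k in {**chemo, **proinfl}}),
        combined: _effects(analytes, {k: 0.4 for k in {**chemo, **proinfl}}),
        "APP_PS1": _effects(analytes, {"IL-6": 0.15, "TNF-a": 0.15}),
    }
    return SyntheticTruth(
        analytes=analytes,
        groups=groups,
        combined_group=combined,
        baseline_log_mean=baseline,
        log_sd=log_sd,
        group_effects=group_effects,
        interaction_effects=interaction,
        noise_correlation=corr,
        lod=lod,
        phenotype_coupling=pheno,
        group_sizes={g: 7 for g in groups},
        seed=seed,
    )
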