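"""Rotated latent-variable profiles and their Monte-Carlo subsampling stability.

After a two-component PLS fit, an orthogonal rotation of the LV1-LV2 plane
picks a new LV1 that maximizes a separation objective (omnibus Welch F
across groups, a designated-group contrast, or correlation with a continuous
phenotype).  Loading stability is then estimated by refitting the whole
pipeline on stratified 80% subsamples, sign-correcting each refit against
the full model, and accumulating per-analyte means and SDs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import CytokinePanel, zscore
from .pls import PLSModel, encode_groups, fit_pls

__all__ = [
    "Objective",
    "RotationResult",
    "LVProfile",
    "AnalysisSpec",
    "rotate_lv_plane",
    "rotation_orthogonality_scan",
    "sign_correct",
    "check_orthogonality",
    "fit_rotated",
    "subsample_profiles",
]

logger = logging.getLogger(__name__)

ORTHOGONALITY_BOUND = 1e-15


@dataclass(frozen=True)
class Objective:
    """Rotation objective: what the new LV1 should separate.

    kind
        ``"group_F"`` — omnibus Welch F of rotated-LV1 scores across groups;
        ``"contrast_separation"`` — difference between the designated group's
        mean score and the pooled mean of the remaining samples;
        ``"phenotype_correlation"`` — |Pearson r| of rotated-LV1 scores with
        a continuous variable.
    positive_group
        Group oriented to score positive on rotated LV1 (contrast and
        group_F modes).
    phenotype
        Name of the continuous variable (phenotype mode).
    """

    kind: str = "contrast_separation"
    positive_group: str | None = None
    phenotype: str | None = None

    def __post_init__(self):
        if self.kind not in ("group_F", "contrast_separation", "phenotype_correlation"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.kind == "contrast_separation" and self.positive_group is None:
            raise ValueError("contrast_separation needs positive_group")
        if self.kind == "phenotype_correlation" and self.phenotype is None:
            raise ValueError("phenotype_correlation needs a phenotype name")


@dataclass
class RotationResult:
    """An optimized in-plane rotation of the first two latent variables."""

    theta: float
    W_rot: np.ndarray  # (p, 2), unit-norm columns
    T_rot: np.ndarray  # (n, 2)
    objective_name: str
    objective_value: float
    flipped: bool = False  # True if LV1 orientation was sign-flipped


@dataclass
class LVProfile:
    """Per-analyte mean +/- SD of a rotated LV weight over subsamples."""

    analytes: list[str]
    mean_signal: np.ndarray
    sd_signal: np.ndarray
    n_iterations: int
    subsample_fraction: float
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_signal": self.mean_signal, "sd_signal": self.sd_signal},
            index=pd.Index(self.analytes, name="analyte"),
        )


@dataclass
class AnalysisSpec:
    """Everything needed to (re)fit standardize -> PLS -> rotate on a panel."""

    mode: str = "plsda"  # "plsda" | "plsr"
    objective: Objective = field(
        default_factory=lambda: Objective(kind="group_F")
    )
    phenotype_values: pd.Series | None = None  # required for plsr
    n_components: int = 2
    grid_points: int = 3601
    reoptimize_rotation: bool = True

    def __post_init__(self):
        if self.mode not in ("plsda", "plsr"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "plsr" and self.phenotype_values is None:
            raise ValueError("plsr mode requires phenotype_values")
        if self.n_components < 2:
            raise ValueError("rotation needs >= 2 components")


def _objective_values(
    scores: np.ndarray,
    objective: Objective,
    groups: np.ndarray | None,
    phenotype: np.ndarray | None,
) -> np.ndarray:
    """Objective evaluated column-wise on an (n, n_angles) score matrix."""
    if objective.kind == "contrast_separation":
        mask = groups == objective.positive_group
        if not mask.any() or mask.all():
            raise ValueError(
                f"contrast group {objective.positive_group!r} is empty "
                "or contains every sample"
            )
        return np.abs(scores[mask].mean(axis=0) - scores[~mask].mean(axis=0))
    if objective.kind == "phenotype_correlation":
        v = phenotype - phenotype.mean()
        sv = np.sqrt((v**2).sum())
        if sv == 0:
            raise ValueError("phenotype is constant; correlation undefined")
        sc = scores - scores.mean(axis=0, keepdims=True)
        denom = np.sqrt((sc**2).sum(axis=0)) * sv
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (sc * v[:, None]).sum(axis=0) / denom, 0.0)
        return np.abs(r)
    # group_F: vectorized Welch omnibus F per column
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("group_F objective needs >= 2 groups")
    w_list, m_list, n_list = [], [], []
    for lv in levels:
        g = scores[groups == lv]
        n_g = g.shape[0]
        m = g.mean(axis=0)
        s2 = g.var(axis=0, ddof=1)
        s2 = np.where(s2 > 0, s2, np.finfo(float).tiny)
        w_list.append(n_g / s2)
        m_list.append(m)
        n_list.append(n_g)
    W = np.array(w_list)  # (k, n_angles)
    M = np.array(m_list)
    k = len(levels)
    w_sum = W.sum(axis=0)
    grand = (W * M).sum(axis=0) / w_sum
    A = (W * (M - grand) ** 2).sum(axis=0) / (k - 1)
    h = ((1 - W / w_sum) ** 2 / (np.array(n_list)[:, None] - 1)).sum(axis=0)
    B = 1 + 2 * (k - 2) / (k**2 - 1) * h
    return A / B


def rotate_lv_plane(
    model: PLSModel,
    objective: Objective,
    *,
    groups=None,
    phenotype=None,
    grid_points: int = 3601,
) -> RotationResult:
    """Grid-search the in-plane rotation angle maximizing the objective.

    The angle grid spans [0, pi) — a rotation by theta + pi is a sign flip,
    which is handled separately by orientation: the designated group (or the
    positive phenotype association) is made to score positive on rotated LV1.
    Input weight columns must be orthonormal; they are re-orthonormalized to
    machine precision (Gram-Schmidt) so every grid rotation keeps
    |w1.w2| <= 1e-15.
    """
    if model.n_components < 2:
        raise ValueError("rotation requires a model with >= 2 components")
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    w1 = model.W[:, 0].copy()
    w2 = model.W[:, 1].copy()
    raw_dot = abs(float(w1 @ w2))
    if raw_dot > 1e-10 or abs(np.linalg.norm(w1) - 1) > 1e-10 or abs(
        np.linalg.norm(w2) - 1
    ) > 1e-10:
        raise ValueError(
            f"input weight pair is not orthonormal (|w1.w2| = {raw_dot:.3e})"
        )
    # polish to machine precision so rotated dot products stay < 1e-15
    w1 /= np.linalg.norm(w1)
    w2 -= (w1 @ w2) * w1
    w2 /= np.linalg.norm(w2)

    groups = None if groups is None else np.asarray(pd.Series(groups).astype(str))
    phenotype = None if phenotype is None else np.asarray(phenotype, dtype=float)
    if objective.kind in ("group_F", "contrast_separation") and groups is None:
        raise ValueError(f"objective {objective.kind} requires group labels")
    if objective.kind == "phenotype_correlation" and phenotype is None:
        raise ValueError("phenotype_correlation requires phenotype values")

    thetas = np.linspace(0.0, np.pi, grid_points, endpoint=False)
    c, s = np.cos(thetas), np.sin(thetas)
    t1, t2 = model.T[:, 0], model.T[:, 1]
    lv1_scores = np.outer(t1, c) + np.outer(t2, s)  # (n, n_angles)
    obj = _objective_values(lv1_scores, objective, groups, phenotype)
    best = int(np.argmax(obj))
    theta = float(thetas[best])

    cb, sb = np.cos(theta), np.sin(theta)
    W_rot = np.column_stack([cb * w1 + sb * w2, -sb * w1 + cb * w2])
    T_rot = np.column_stack([cb * t1 + sb * t2, -sb * t1 + cb * t2])

    # orientation: designated group / positive association scores positive
    flipped = False
    if objective.kind in ("contrast_separation", "group_F"):
        ref = (
            objective.positive_group
            if objective.positive_group is not None
            else pd.unique(groups)[-1]
        )
        mask = groups == ref
        if mask.any() and T_rot[mask, 0].mean() < T_rot[~mask, 0].mean():
            flipped = True
    else:
        v = phenotype - phenotype.mean()
        if float(T_rot[:, 0] @ v) < 0:
            flipped = True
    if flipped:
        W_rot[:, 0] *= -1
        T_rot[:, 0] *= -1

    return RotationResult(
        theta=theta,
        W_rot=W_rot,
        T_rot=T_rot,
        objective_name=objective.kind,
        objective_value=float(obj[best]),
        flipped=flipped,
    )


def rotation_orthogonality_scan(
    model: PLSModel, grid_points: int = 3601
) -> float:
    """Max |w1.w2| of the rotated weight pair over every grid angle.

    Applies the same orthonormality polish as :func:`rotate_lv_plane` and
    sweeps the full angle grid; used to verify that the rotation can never
    break the orthogonality bound regardless of the selected angle.
    """
    w1 = model.W[:, 0].copy()
    w2 = model.W[:, 1].copy()
    w1 /= np.linalg.norm(w1)
    w2 -= (w1 @ w2) * w1
    w2 /= np.linalg.norm(w2)
    worst = 0.0
    for th in np.linspace(0.0, np.pi, grid_points, endpoint=False):
        c, s = np.cos(th), np.sin(th)
        dot = abs(float((c * w1 + s * w2) @ (-s * w1 + c * w2)))
        worst = max(worst, dot)
    return worst


def sign_correct(subsample_lv: np.ndarray, reference_lv: np.ndarray) -> np.ndarray:
    """Align a subsampled LV with the full-model LV by flipping its sign.

    Multiplies the subsampled vector by the sign of its scalar product with
    the reference, so the output satisfies ``output . reference >= 0``.
    """
    subsample_lv = np.asarray(subsample_lv, dtype=float)
    reference_lv = np.asarray(reference_lv, dtype=float)
    if subsample_lv.shape != reference_lv.shape:
        raise ValueError("vectors have different lengths")
    if not np.any(reference_lv):
        raise ValueError("reference vector is zero")
    dot = float(subsample_lv @ reference_lv)
    if dot == 0.0:
        warnings.warn("zero scalar product; keeping original sign", stacklevel=2)
        return subsample_lv.copy()
    return subsample_lv * np.sign(dot)


def check_orthogonality(
    result: RotationResult, bound: float = ORTHOGONALITY_BOUND
) -> float:
    """Return |w1.w2| of the rotated pair; hard error if it exceeds the bound."""
    dot = abs(float(result.W_rot[:, 0] @ result.W_rot[:, 1]))
    if dot > bound:
        raise ValueError(
            f"rotated components not orthogonal: |w1.w2| = {dot:.3e} > {bound:.0e}"
        )
    return dot


def _fit_once(
    panel: CytokinePanel, spec: AnalysisSpec
) -> tuple[PLSModel, RotationResult]:
    """standardize -> PLS -> rotate on one (sub)panel."""
    Z = zscore(panel)
    groups = panel.group.to_numpy(dtype=object)
    phen = None
    if spec.mode == "plsda":
        Y, levels = encode_groups(panel.group)
        y_encoding = ("indicator", levels)
    else:
        phen = spec.phenotype_values.reindex(panel.values.index)
        if phen.isna().any():
            bad = phen.index[phen.isna()].tolist()
            raise ValueError(f"phenotype missing for samples: {bad}")
        phen = phen.to_numpy(dtype=float)
        Y = phen - phen.mean()
        y_encoding = "continuous"
    model = fit_pls(
        Z,
        Y,
        n_components=spec.n_components,
        y_encoding=y_encoding,
        x_center=panel.values.loc[Z.index].mean(axis=0).to_numpy(),
        x_scale=panel.values.loc[Z.index].std(axis=0, ddof=1).to_numpy(),
    )
    rotation = rotate_lv_plane(
        model,
        spec.objective,
        groups=groups,
        phenotype=phen,
        grid_points=spec.grid_points,
    )
    check_orthogonality(rotation)
    return model, rotation


def fit_rotated(
    panel: CytokinePanel, spec: AnalysisSpec
) -> tuple[PLSModel, RotationResult]:
    """Fit the full model on all samples and rotate it."""
    return _fit_once(panel, spec)


def _fit_rotate_arrays(
    X_raw: np.ndarray,
    groups: np.ndarray,
    phen: np.ndarray | None,
    spec: AnalysisSpec,
    levels: list[str] | None,
) -> RotationResult:
    """Numpy fast path of standardize -> PLS -> rotate for subsample refits."""
    sd = X_raw.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance analyte in subsample")
    Z = (X_raw - X_raw.mean(axis=0)) / sd
    if spec.mode == "plsda":
        counts = {lv: int((groups == lv).sum()) for lv in levels}
        if any(c < 2 for c in counts.values()):
            raise ValueError(f"group collapse in subsample: {counts}")
        Y = np.stack([(groups == lv).astype(float) for lv in levels], axis=1)
        Y -= Y.mean(axis=0, keepdims=True)
    else:
        Y = phen - phen.mean()
    model = fit_pls(Z, Y, n_components=spec.n_components)
    rot = rotate_lv_plane(
        model,
        spec.objective,
        groups=groups,
        phenotype=phen,
        grid_points=spec.grid_points,
    )
    check_orthogonality(rot)
    return rot


def _stratified_indices(
    groups: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Without-replacement subsample of round(fraction*n_g) per group, min 2.

    Indices are returned sorted so that fraction=1.0 reproduces the original
    sample order exactly (bitwise-identical refits).
    """
    chosen: list[np.ndarray] = []
    for lv in pd.unique(groups):
        idx = np.flatnonzero(groups == lv)
        k = max(2, int(round(fraction * len(idx))))
        k = min(k, len(idx))
        chosen.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(chosen))


def subsample_profiles(
    panel: CytokinePanel,
    spec: AnalysisSpec,
    fraction: float = 0.8,
    iterations: int = 1000,
    seed: int | None = 0,
    *,
    max_consecutive_failures: int = 100,
) -> tuple[LVProfile, LVProfile]:
    """Monte-Carlo subsampling stability of the rotated LV1/LV2 weights.

    Each iteration draws a stratified without-replacement subsample of the
    requested fraction, re-standardizes within it, refits the PLS model,
    re-rotates (or reuses the full-model angle, per ``spec``), sign-corrects
    both LVs against the full model, and accumulates per-analyte weights.
    Returns (LV1 profile, LV2 profile) with mean and SD per analyte.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    groups = panel.group.to_numpy(dtype=object)
    for lv in pd.unique(groups):
        n_g = int((groups == lv).sum())
        if max(2, int(round(fraction * n_g))) > n_g:
            raise ValueError(
                f"group {lv!r} has {n_g} samples; cannot retain >= 2 at "
                f"fraction {fraction}"
            )

    _, full_rotation = _fit_once(panel, spec)
    ref_lv1 = full_rotation.W_rot[:, 0]
    ref_lv2 = full_rotation.W_rot[:, 1]

    # raw arrays for the refit loop; pandas indexing is too slow at 1000x
    X_all = panel.values.to_numpy(dtype=float)
    groups_str = panel.group.astype(str).to_numpy(dtype=object)
    levels = list(pd.unique(groups_str))
    phen_all = None
    if spec.mode == "plsr":
        phen_all = (
            spec.phenotype_values.reindex(panel.values.index).to_numpy(dtype=float)
        )

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(iterations)
    p = panel.n_analytes
    acc1 = np.zeros((iterations, p))
    acc2 = np.zeros((iterations, p))

    for i in range(iterations):
        rng = np.random.default_rng(child_seeds[i])
        for attempt in range(max_consecutive_failures + 1):
            idx = _stratified_indices(groups_str, fraction, rng)
            Xs = X_all[idx]
            gs = groups_str[idx]
            ps = None if phen_all is None else phen_all[idx]
            try:
                if spec.reoptimize_rotation:
                    rot = _fit_rotate_arrays(Xs, gs, ps, spec, levels)
                    w1, w2 = rot.W_rot[:, 0], rot.W_rot[:, 1]
                else:
                    sd = Xs.std(axis=0, ddof=1)
                    if (sd == 0).any():
                        raise ValueError("zero-variance analyte in subsample")
                    Z = (Xs - Xs.mean(axis=0)) / sd
                    if spec.mode == "plsda":
                        Y = np.stack(
                            [(gs == lv).astype(float) for lv in levels], axis=1
                        )
                        if (Y.sum(axis=0) < 2).any():
                            raise ValueError("group collapse in subsample")
                        Y -= Y.mean(axis=0, keepdims=True)
                    else:
                        Y = ps - ps.mean()
                    m = fit_pls(Z, Y, n_components=spec.n_components)
                    th = full_rotation.theta
                    cb, sb = np.cos(th), np.sin(th)
                    w1 = cb * m.W[:, 0] + sb * m.W[:, 1]
                    w2 = -sb * m.W[:, 0] + cb * m.W[:, 1]
                break
            except (ValueError, RuntimeError) as exc:
                logger.info("iteration %d resampled after failure: %s", i, exc)
                if attempt == max_consecutive_failures:
                    raise RuntimeError(
                        f"{max_consecutive_failures} consecutive refit "
                        f"failures at iteration {i}; last error: {exc}"
                    ) from exc
        acc1[i] = sign_correct(w1, ref_lv1)
        acc2[i] = sign_correct(w2, ref_lv2)

    def _profile(acc: np.ndarray) -> LVProfile:
        if iterations > 1:
            sd = acc.std(axis=0, ddof=1)
            # identical draws (e.g. fraction = 1.0) have SD exactly zero;
            # avoid spurious rounding from the mean subtraction
            sd[np.ptp(acc, axis=0) == 0] = 0.0
        else:
            sd = np.zeros(p)
        return LVProfile(
            analytes=panel.analytes,
            mean_signal=acc.mean(axis=0),
            sd_signal=sd,
            n_iterations=iterations,
            subsample_fraction=fraction,
            seed=seed,
        )

    return _profile(acc1), _profile(acc2)
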