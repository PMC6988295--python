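"""NIPALS partial least squares (regression and discriminant modes).

Implements PLS2 with X-deflation only: weight vectors are unit-norm and
mutually orthogonal, scores are orthogonal, and the response is never
deflated.  The discriminant mode encodes group labels as column-centered
indicator columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "encode_groups",
    "fit_pls",
    "project",
    "variance_explained",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    """Fitted latent-variable decomposition.

    Attributes
    ----------
    W : (p, a) weight matrix, unit-norm columns; column k is LV(k+1).
    P : (p, a) X-loading matrix.
    Q : (m, a) Y-loading matrix.
    T : (n, a) sample score matrix (projections of the deflated X).
    x_columns : analyte names in fitting order.
    y_encoding : "continuous", or ("indicator", [level order]) for PLSDA.
    x_center, x_scale : standardization constants applied to X before the fit.
    """

    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    x_columns: list[str]
    y_encoding: object = "continuous"
    x_center: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def save_model(model: PLSModel, directory) -> None:
    """Serialize a fitted model as a JSON + CSV bundle."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    comps = [f"LV{a + 1}" for a in range(model.n_components)]
    for name, mat in (("W", model.W), ("P", model.P)):
        pd.DataFrame(mat, index=model.x_columns, columns=comps).to_csv(
            directory / f"{name}.csv"
        )
    pd.DataFrame(model.Q, columns=comps).to_csv(directory / "Q.csv")
    t_index = model.sample_ids if model.sample_ids else range(model.T.shape[0])
    pd.DataFrame(model.T, index=t_index, columns=comps).to_csv(
        directory / "T.csv"
    )
    meta = {
        "x_columns": model.x_columns,
        "y_encoding": model.y_encoding
        if isinstance(model.y_encoding, str)
        else list(model.y_encoding),
        "n_components": model.n_components,
        "sample_ids": model.sample_ids,
        "x_center": None if model.x_center is None else model.x_center.tolist(),
        "x_scale": None if model.x_scale is None else model.x_scale.tolist(),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> PLSModel:
    """Load a model bundle written by :func:`save_model`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    read = lambda name: pd.read_csv(directory / f"{name}.csv", index_col=0).to_numpy()
    enc = meta["y_encoding"]
    if isinstance(enc, list):
        enc = (enc[0], enc[1])
    return PLSModel(
        W=read("W"),
        P=read("P"),
        Q=read("Q"),
        T=read("T"),
        x_columns=meta["x_columns"],
        y_encoding=enc,
        x_center=None if meta["x_center"] is None else np.array(meta["x_center"]),
        x_scale=None if meta["x_scale"] is None else np.array(meta["x_scale"]),
        sample_ids=meta["sample_ids"],
    )


def encode_groups(labels) -> tuple[np.ndarray, list[str]]:
    """Encode categorical labels as column-centered indicator columns.

    Returns the centered indicator matrix (one column per level, in order of
    first appearance) and the level order.
    """
    labels = np.asarray(pd.Series(labels).astype(str))
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError(f"need >= 2 group levels, got {levels}")
    counts = {lv: int((labels == lv).sum()) for lv in levels}
    small = [lv for lv, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with < 2 samples: {small}")
    Y = np.stack([(labels == lv).astype(float) for lv in levels], axis=1)
    Y -= Y.mean(axis=0, keepdims=True)
    return Y, levels


def fit_pls(
    X,
    Y,
    n_components: int = 2,
    *,
    tol: float = 1e-12,
    max_iter: int = 500,
    y_encoding: object = "continuous",
    x_center: np.ndarray | None = None,
    x_scale: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS2 model by NIPALS with X-deflation.

    ``X`` must be column-standardized and ``Y`` centered; neither may contain
    missing values.  The inner loop is initialized with the Y column of
    largest variance, making the fit deterministic.  Stops early with a
    warning if X is exhausted (residual norm below 1e-12) before
    ``n_components`` are extracted.
    """
    x_columns = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    sample_ids = (
        [str(i) for i in X.index] if isinstance(X, pd.DataFrame) else []
    )
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y have different sample counts")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values in X or Y")
    if np.allclose(Y, 0.0):
        raise ValueError("response is constant (all zero after centering)")
    max_rank = min(n - 1, p)
    if n_components < 1 or n_components > max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for this problem size"
        )

    Xd = X.copy()
    Ws, Ps, Qs, Ts = [], [], [], []
    for a in range(n_components):
        if np.linalg.norm(Xd) < 1e-12:
            warnings.warn(
                f"X exhausted after {a} components; requested {n_components}",
                stacklevel=2,
            )
            break
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if Y.shape[1] == 1:
            # univariate response: u = y is a fixed point, no iteration needed
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise RuntimeError(
                    f"NIPALS breakdown at component {a + 1}: zero weight vector"
                )
            w /= nw
            t = Xd @ w
            tt = t @ t
            p_load = Xd.T @ t / tt
            q = Y.T @ t / tt
            Xd = Xd - np.outer(t, p_load)
            Ws.append(w)
            Ps.append(p_load)
            Qs.append(q)
            Ts.append(t)
            continue
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                raise RuntimeError(
                    f"NIPALS breakdown at component {a + 1}: zero weight vector"
                )
            w_new /= nw
            if w @ w_new < 0:
                # sign indeterminacy can produce a flip-flop 2-cycle; pin the
                # orientation to the first iterate
                w_new = -w_new
            t = Xd @ w_new
            tt = t @ t
            if tt == 0:
                raise RuntimeError(
                    f"NIPALS breakdown at component {a + 1}: zero scores"
                )
            q = Y.T @ t / tt
            qq = q @ q
            u = Y @ q / qq if qq > 0 else t
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        else:
            raise RuntimeError(
                f"NIPALS did not converge for component {a + 1} "
                f"within {max_iter} iterations"
            )
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        q = Y.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Ws.append(w)
        Ps.append(p_load)
        Qs.append(q)
        Ts.append(t)

    return PLSModel(
        W=np.column_stack(Ws),
        P=np.column_stack(Ps),
        Q=np.column_stack(Qs),
        T=np.column_stack(Ts),
        x_columns=x_columns,
        y_encoding=y_encoding,
        x_center=None if x_center is None else np.asarray(x_center, float),
        x_scale=None if x_scale is None else np.asarray(x_scale, float),
        sample_ids=sample_ids,
    )


def project(model: PLSModel, X_new) -> np.ndarray:
    """Score new standardized samples on the fitted components.

    Replays the fit's deflation: ``t_a = X_def w_a`` then
    ``X_def -= t_a p_a^T``.  Projecting the training matrix reproduces the
    stored scores.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.x_columns if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in model.x_columns]
        if missing or extra:
            raise ValueError(
                f"analyte mismatch: missing {missing}, unexpected {extra}"
            )
        X_new = X_new[model.x_columns]
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"expected {model.W.shape[0]} analyte columns, got {X_new.shape[1]}"
        )
    Xd = X_new.copy()
    scores = np.empty((X_new.shape[0], model.n_components))
    for a in range(model.n_components):
        t = Xd @ model.W[:, a]
        scores[:, a] = t
        Xd -= np.outer(t, model.P[:, a])
    return scores


def variance_explained(model: PLSModel, X, Y) -> dict[str, np.ndarray]:
    """Per-component fractions of X and Y variance captured by the model."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    ss_x = float((X**2).sum())
    ss_y = float((Y**2).sum())
    frac_x = np.empty(model.n_components)
    frac_y = np.empty(model.n_components)
    Y_res = Y.copy()
    for a in range(model.n_components):
        t = model.T[:, a]
        frac_x[a] = (t @ t) * float(model.P[:, a] @ model.P[:, a]) / ss_x
        Y_prev = float((Y_res**2).sum())
        Y_res = Y_res - np.outer(t, model.Q[:, a])
        frac_y[a] = (Y_prev - float((Y_res**2).sum())) / ss_y
    return {"x": np.clip(frac_x, 0.0, 1.0), "y": np.clip(frac_y, 0.0, 1.0)}
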