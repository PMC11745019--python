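"""Two-block association analysis: cross-block Pearson screening and sparse
partial least squares (sPLS) projection to latent structures.

Both blocks are variable x sample tables sharing the same sample columns
(e.g. genome abundances vs eukaryote abundances). ``pearson_matrix`` screens
all cross-block pairs against a correlation cutoff; :class:`SparsePLS` fits
the canonical two-block sPLS (NIPALS iterations with soft-thresholding of
the weight vectors, as formulated by Lê Cao and co-workers), whose first
latent pair maximizes the covariance between linear combinations of the two
blocks while sparsity limits how many variables carry nonzero weight. The
fitted :class:`SPLSResults` exposes weights, sample scores, loadings,
convergence diagnostics and the correlation-circle coordinates used to read
off co-varying variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "pearson_matrix",
    "SparsePLS",
    "SPLSResults",
    "ConvergenceError",
    "correlation_circle",
    "relative_abundance",
]


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge; carries the per-iteration change trace."""

    def __init__(self, component: int, trace: list[float]):
        self.component = component
        self.trace = trace
        super().__init__(
            f"sPLS component {component + 1} did not converge in {len(trace)} iterations "
            f"(last change {trace[-1]:.3e})"
        )


def relative_abundance(block: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample column to sum to 1 (all-zero columns left as 0)."""
    sums = block.sum(axis=0)
    safe = sums.replace(0, np.nan)
    return block.div(safe, axis=1).fillna(0.0)


def _align_blocks(X: pd.DataFrame, Y: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if list(X.columns) != list(Y.columns):
        if set(X.columns) == set(Y.columns):
            Y = Y[X.columns]
        else:
            raise ValueError("the two blocks must share the same sample columns")
    na_cols = X.columns[X.isna().any(axis=0).to_numpy() | Y.isna().any(axis=0).to_numpy()]
    if len(na_cols):
        warnings.warn(
            f"dropping {len(na_cols)} sample(s) with missing values: {list(na_cols[:5])}",
            stacklevel=3,
        )
        X = X.drop(columns=na_cols)
        Y = Y.drop(columns=na_cols)
    return X, Y


def pearson_matrix(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """All cross-block Pearson correlations with |r| >= cutoff.

    Rows of X and Y are variables, columns are shared samples (>= 3 needed).
    Constant rows have undefined r and are excluded.
    """
    X, Y = _align_blocks(X, Y)
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 shared samples for correlation")

    def _standardize(block: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        arr = block.to_numpy(dtype=float)
        mean = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        ok = sd.ravel() > 0
        zs = np.zeros_like(arr)
        zs[ok] = (arr[ok] - mean[ok]) / sd[ok]
        return zs, ok

    zx, okx = _standardize(X)
    zy, oky = _standardize(Y)
    r = zx @ zy.T / (n - 1)
    rows = []
    for i, var_a in enumerate(X.index):
        if not okx[i]:
            continue
        for j, var_b in enumerate(Y.index):
            if not oky[j]:
                continue
            if abs(r[i, j]) >= cutoff:
                rows.append({"var_a": var_a, "var_b": var_b, "r": float(r[i, j])})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r"])


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold a weight vector so exactly ``keep`` entries survive.

    The threshold is the (keep+1)-th largest absolute value; surviving
    entries are shrunk toward zero by it (the LASSO-style update of sPLS).
    """
    p = w.size
    if keep >= p:
        return w
    magnitudes = np.abs(w)
    lam = np.sort(magnitudes)[::-1][keep]
    out = np.sign(w) * np.maximum(magnitudes - lam, 0.0)
    return out


@dataclass
class SPLSResults:
    """Fitted sPLS decomposition.

    Weight matrices are variables x components (unit-norm columns); scores
    are samples x components. ``n_iter``/``converged`` record the NIPALS
    diagnostics per component.
    """

    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    x_scores: pd.DataFrame
    y_scores: pd.DataFrame
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    n_iter: list[int]
    converged: list[bool]
    mode: str
    keep_x: list[int] = field(default_factory=list)
    keep_y: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def score_correlations(self) -> np.ndarray:
        """Pearson correlation between paired X and Y scores, per component."""
        out = []
        for h in range(self.n_components):
            t = self.x_scores.iloc[:, h]
            u = self.y_scores.iloc[:, h]
            out.append(float(np.corrcoef(t, u)[0, 1]))
        return np.asarray(out)

    def summary(self) -> str:
        lines = [
            "Sparse PLS results",
            f"  mode: {self.mode}   components: {self.n_components}",
            f"  block X: {self.x_weights.shape[0]} variables   "
            f"block Y: {self.y_weights.shape[0]} variables   "
            f"samples: {self.x_scores.shape[0]}",
            "  comp   keepX  keepY  iters  converged  cov(t,u)      cor(t,u)",
        ]
        for h in range(self.n_components):
            t = self.x_scores.iloc[:, h].to_numpy()
            u = self.y_scores.iloc[:, h].to_numpy()
            cov = float(t @ u) / (len(t) - 1)
            cor = self.score_correlations()[h]
            lines.append(
                f"  {h + 1:>4}   {self.keep_x[h]:>5}  {self.keep_y[h]:>5}  "
                f"{self.n_iter[h]:>5}  {str(self.converged[h]):>9}  "
                f"{cov:>12.4g}  {cor:>12.4f}"
            )
        return "\n".join(lines)

    def variates_frame(self) -> pd.DataFrame:
        t = self.x_scores.add_prefix("X_")
        u = self.y_scores.add_prefix("Y_")
        return pd.concat([t, u], axis=1).rename_axis("sample_id").reset_index()


class SparsePLS:
    """Two-block sparse PLS model (canonical mode by default).

    Parameters
    ----------
    n_components : number of latent component pairs to extract.
    keep_x, keep_y : number of variables with nonzero weight per component
        (one value per component, or a scalar reused for all); ``None``
        keeps every variable, reducing to dense PLS.
    mode : 'canonical' (both blocks deflated on their own scores; the
        symmetric choice for relating two communities) or 'regression'
        (Y deflated on the X scores).
    scale : center each variable and scale to unit variance before fitting.
    """

    def __init__(
        self,
        n_components: int = 2,
        keep_x: int | list[int] | None = None,
        keep_y: int | list[int] | None = None,
        mode: str = "canonical",
        scale: bool = True,
        max_iter: int = 500,
        tol: float = 1e-9,
    ):
        if mode not in ("canonical", "regression"):
            raise ValueError(f"unknown mode {mode!r}")
        self.n_components = int(n_components)
        self.keep_x = keep_x
        self.keep_y = keep_y
        self.mode = mode
        self.scale = scale
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    def _expand_keep(self, keep, p: int, name: str) -> list[int]:
        if keep is None:
            return [p] * self.n_components
        if np.isscalar(keep):
            keep = [int(keep)] * self.n_components
        keep = [int(k) for k in keep]
        if len(keep) != self.n_components:
            raise ValueError(f"{name} needs one value per component")
        out = []
        for k in keep:
            if k < 1:
                raise ValueError(f"{name} entries must be >= 1")
            if k > p:
                warnings.warn(f"{name}={k} exceeds {p} variables; clamped", stacklevel=3)
                k = p
            out.append(k)
        return out

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame) -> SPLSResults:
        """Fit on two variable x sample blocks sharing sample columns."""
        X, Y = _align_blocks(X, Y)
        n = X.shape[1]
        if n < 3:
            raise ValueError("need at least 3 samples to fit")
        if self.n_components < 1 or self.n_components > n - 1:
            raise ValueError(f"n_components must be in [1, {n - 1}]")
        keep_x = self._expand_keep(self.keep_x, X.shape[0], "keep_x")
        keep_y = self._expand_keep(self.keep_y, Y.shape[0], "keep_y")

        def _prepare(block: pd.DataFrame) -> np.ndarray:
            arr = block.to_numpy(dtype=float).T  # samples x variables
            arr = arr - arr.mean(axis=0, keepdims=True)
            if self.scale:
                sd = arr.std(axis=0, ddof=1, keepdims=True)
                arr = arr / np.where(sd == 0, 1.0, sd)
            return arr

        Xc, Yc = _prepare(X), _prepare(Y)

        p, q = Xc.shape[1], Yc.shape[1]
        W = np.zeros((p, self.n_components))
        C = np.zeros((q, self.n_components))
        T = np.zeros((n, self.n_components))
        U = np.zeros((n, self.n_components))
        P = np.zeros((p, self.n_components))
        Q = np.zeros((q, self.n_components))
        n_iter: list[int] = []
        converged: list[bool] = []

        for h in range(self.n_components):
            M = Xc.T @ Yc
            # initialize from the dominant singular pair of the cross-covariance
            u_init, _, vt = np.linalg.svd(M, full_matrices=False)
            w = u_init[:, 0]
            c = vt[0]
            u = Yc @ c
            trace: list[float] = []
            for it in range(self.max_iter):
                w_old, c_old = w, c
                w = Xc.T @ u
                w = _soft_threshold_keep(w, keep_x[h])
                norm = np.linalg.norm(w)
                if norm == 0:
                    raise ConvergenceError(h, trace or [np.inf])
                w = w / norm
                t = Xc @ w
                c = Yc.T @ t
                c = _soft_threshold_keep(c, keep_y[h])
                norm = np.linalg.norm(c)
                if norm == 0:
                    raise ConvergenceError(h, trace or [np.inf])
                c = c / norm
                u = Yc @ c
                change = max(np.abs(w - w_old).max(), np.abs(c - c_old).max())
                trace.append(change)
                if change < self.tol:
                    break
            else:
                raise ConvergenceError(h, trace)
            n_iter.append(len(trace))
            converged.append(trace[-1] < self.tol)

            # reproducible sign: largest-magnitude X weight positive
            flip = np.sign(w[np.argmax(np.abs(w))]) or 1.0
            w, t = w * flip, t * flip
            flip_c = np.sign(c[np.argmax(np.abs(c))]) or 1.0
            c, u = c * flip_c, u * flip_c

            p_load = Xc.T @ t / (t @ t)
            Xc = Xc - np.outer(t, p_load)
            if self.mode == "canonical":
                q_load = Yc.T @ u / (u @ u)
                Yc = Yc - np.outer(u, q_load)
            else:
                q_load = Yc.T @ t / (t @ t)
                Yc = Yc - np.outer(t, q_load)
            W[:, h], C[:, h], T[:, h], U[:, h] = w, c, t, u
            P[:, h], Q[:, h] = p_load, q_load

        comps = [f"comp{h + 1}" for h in range(self.n_components)]
        samples = list(X.columns)
        return SPLSResults(
            x_weights=pd.DataFrame(W, index=X.index, columns=comps),
            y_weights=pd.DataFrame(C, index=Y.index, columns=comps),
            x_scores=pd.DataFrame(T, index=samples, columns=comps),
            y_scores=pd.DataFrame(U, index=samples, columns=comps),
            x_loadings=pd.DataFrame(P, index=X.index, columns=comps),
            y_loadings=pd.DataFrame(Q, index=Y.index, columns=comps),
            n_iter=n_iter,
            converged=converged,
            mode=self.mode,
            keep_x=keep_x,
            keep_y=keep_y,
        )


def spls_fit(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_components: int = 2,
    keep_x: int | list[int] | None = None,
    keep_y: int | list[int] | None = None,
    **kwargs,
) -> SPLSResults:
    """Functional wrapper around :class:`SparsePLS`."""
    return SparsePLS(
        n_components=n_components, keep_x=keep_x, keep_y=keep_y, **kwargs
    ).fit(X, Y)


def correlation_circle(
    results: SPLSResults,
    X: pd.DataFrame,
    Y: pd.DataFrame,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Correlation of every variable with its block's first two variates.

    Variables are retained when either coordinate reaches |r| >= cutoff.
    Coordinates lie in the unit disc (up to numerical tolerance).
    """
    if results.n_components < 2:
        raise ValueError("correlation circle needs a model with >= 2 components")
    X, Y = _align_blocks(X, Y)

    def _coords(block: pd.DataFrame, scores: pd.DataFrame, name: str) -> pd.DataFrame:
        arr = block.to_numpy(dtype=float)
        rows = []
        for i, var in enumerate(block.index):
            x = arr[i]
            if x.std(ddof=1) == 0:
                c1 = c2 = np.nan
            else:
                c1 = float(np.corrcoef(x, scores.iloc[:, 0])[0, 1])
                c2 = float(np.corrcoef(x, scores.iloc[:, 1])[0, 1])
            retained = bool(max(abs(c1), abs(c2)) >= cutoff) if np.isfinite(c1) else False
            rows.append(
                {"variable": var, "block": name, "comp1": c1, "comp2": c2, "retained": retained}
            )
        return pd.DataFrame(rows)

    return pd.concat(
        [_coords(X, results.x_scores, "X"), _coords(Y, results.y_scores, "Y")],
        ignore_index=True,
    )
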