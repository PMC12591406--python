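"""Matrix regression of associations on dyadic predictors with QAP inference.

The response (the SRI association matrix) is regressed by OLS on pairwise
predictor matrices over all ordered off-diagonal dyads.  Because dyads
sharing an individual are not independent, significance comes from the
quadratic assignment procedure: the response's rows and columns are
simultaneously permuted by a random relabeling of individuals, the model is
refit, and each coefficient's two-tailed p-value is the +1-corrected
fraction of permuted |beta| values at least as large as the observed one.

Predictor construction from per-individual habitat covariates follows the
"similarity" convention: M[i,j] = -|v_i - v_j|, z-scored over off-diagonal
entries, so a positive coefficient means individuals with similar habitat
associate more.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .association import AssociationMatrix

__all__ = [
    "PredictorMatrix",
    "MRQAPResult",
    "build_predictor",
    "same_group_predictor",
    "geographic_predictor",
    "fit_mrqap",
]


class ConstantPredictorError(ValueError):
    """The predictor has zero variance over off-diagonal entries."""


@dataclass
class PredictorMatrix:
    """A named symmetric dyadic predictor aligned to the response ids."""

    name: str
    values: np.ndarray  # symmetric, zero diagonal, finite

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"{self.name}: non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError(f"{self.name}: not symmetric")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = v


@dataclass
class MRQAPResult:
    """Coefficients, fit statistics, and QAP permutation p-values."""

    predictor_names: list[str]
    beta: np.ndarray  # slope per predictor (intercept not included)
    intercept: float
    adj_r2: float
    f_stat: float
    p_perm: np.ndarray  # two-tailed QAP p per predictor, in (0, 1]
    n_perm: int
    seed: int
    n: int  # individuals
    collinear: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictor_names,
            "beta": [float(b) for b in self.beta],
            "intercept": self.intercept,
            "adj_r2": self.adj_r2,
            "f_stat": self.f_stat,
            "p_perm": [float(p) for p in self.p_perm],
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_individuals": self.n,
            "collinear": self.collinear,
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _offdiag_z(m: np.ndarray, name: str) -> np.ndarray:
    off = ~np.eye(m.shape[0], dtype=bool)
    mu = m[off].mean()
    sd = m[off].std()
    if sd == 0:
        raise ConstantPredictorError(f"{name}: constant over off-diagonal entries")
    out = (m - mu) / sd
    np.fill_diagonal(out, 0.0)
    return out


def build_predictor(
    values: np.ndarray, name: str, method: str = "neg_abs_diff_z"
) -> PredictorMatrix:
    """Dyadic similarity predictor from one summary value per individual.

    ``neg_abs_diff_z``: M[i,j] = -|v_i - v_j| z-scored over off-diagonal
    entries (higher = more similar).  Raises if all values are equal.
    """
    v = np.asarray(values, dtype=float)
    if method != "neg_abs_diff_z":
        raise ValueError(f"unknown method {method!r}")
    raw = -np.abs(v[:, None] - v[None, :])
    return PredictorMatrix(name=name, values=_offdiag_z(raw, name))


def same_group_predictor(group_ids: list, name: str = "same_matriline") -> PredictorMatrix:
    """Indicator predictor: 1 if two individuals share a group label, else 0.

    Rejected as constant if every pair (or no pair) shares a group.
    """
    g = np.asarray(group_ids)
    raw = (g[:, None] == g[None, :]).astype(float)
    np.fill_diagonal(raw, 0.0)
    off = ~np.eye(len(g), dtype=bool)
    if raw[off].std() == 0:
        raise ConstantPredictorError(f"{name}: all pairs identical")
    return PredictorMatrix(name=name, values=raw)


def geographic_predictor(
    lat: np.ndarray,
    lon: np.ndarray,
    name: str = "geographic_proximity",
    combined: bool = True,
) -> PredictorMatrix | tuple[PredictorMatrix, PredictorMatrix]:
    """Geographic similarity from mean encounter positions.

    Default: one combined matrix of minus the great-circle distance between
    individuals' mean positions, z-scored (higher = closer).  With
    ``combined=False`` returns separate latitude and longitude similarity
    matrices instead.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not combined:
        return build_predictor(lat, f"{name}_lat"), build_predictor(lon, f"{name}_lon")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    gc_km = 2 * 6371.0 * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return PredictorMatrix(name=name, values=_offdiag_z(-gc_km, name))


def fit_mrqap(
    Y: AssociationMatrix | np.ndarray,
    Xs: list[PredictorMatrix],
    n_perm: int = 1000,
    seed: int = 0,
    condition_threshold: float = 1e8,
) -> MRQAPResult:
    """OLS of the association matrix on predictor matrices with QAP-Y inference.

    All n(n-1) ordered off-diagonal dyads enter the regression (with an
    intercept).  The null distribution simultaneously permutes the rows and
    columns of the response with a fresh random relabeling per replicate;
    predictors stay fixed.  p_k = (1 + #{|beta*_k| >= |beta_k|}) / (1 + n_perm).
    """
    if isinstance(Y, AssociationMatrix):
        y_mat = Y.sri.copy()
    else:
        y_mat = np.asarray(Y, dtype=float).copy()
    n = y_mat.shape[0]
    if n < 5:
        raise ValueError("need at least 5 individuals for MRQAP")
    if not Xs:
        raise ValueError("no predictors")
    np.fill_diagonal(y_mat, 0.0)

    off = ~np.eye(n, dtype=bool)
    design = np.column_stack([np.ones(off.sum())] + [x.values[off] for x in Xs])
    y = y_mat[off]

    notes: list[str] = []
    cond = np.linalg.cond(design)
    collinear = bool(cond > condition_threshold)
    if collinear:
        warnings.warn(
            f"predictor design is near-collinear (condition number {cond:.3g}); "
            "pseudo-inverse fit",
            stacklevel=2,
        )
        notes.append(f"collinear design, cond={cond:.3g}")
    pinv = np.linalg.pinv(design)
    coefs = pinv @ y
    fitted = design @ coefs
    resid = y - fitted
    n_obs = len(y)
    k = len(Xs)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - k - 1)
    if ss_res > 0:
        f_stat = ((ss_tot - ss_res) / k) / (ss_res / (n_obs - k - 1))
    else:
        f_stat = np.inf

    beta_obs = coefs[1:]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = y_mat[np.ix_(perm, perm)][off]
        beta_perm = (pinv @ y_perm)[1:]
        exceed += np.abs(beta_perm) >= np.abs(beta_obs)
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    return MRQAPResult(
        predictor_names=[x.name for x in Xs],
        beta=beta_obs,
        intercept=float(coefs[0]),
        adj_r2=float(adj_r2),
        f_stat=float(f_stat),
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
        n=n,
        collinear=collinear,
        notes=notes,
    )
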