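"""Variance-component models, model selection, BLUPs and heritability.

Each trait observation is modelled with an intercept plus independent
Gaussian random effects,

    Y = Intercept + Accession (+ Block) (+ Column) (+ Row) + Residual,

where Accession carries the genetic variance V_G and the spatial terms absorb
field heterogeneity. Because columns are nested in blocks, the full model
would be overparameterized; six reduced structures are fitted instead
(Accession alone, plus Block, Column, Row, Block+Row, or Column+Row) and the
one with the lowest AIC is kept.

Estimation is restricted maximum likelihood (REML): the restricted likelihood
is profiled over the variance ratios γ_k = σ²_k/σ²_R, with the residual
variance solved in closed form at each γ, and maximized by L-BFGS-B with an
analytic gradient under γ_k ≥ 0 bounds. Fits are deterministic: fixed
starting values (equal split of the total variance, γ = 1) and a 1e-8
convergence tolerance on the objective.

From the selected fit: BLUP_i = intercept + u_i (the predicted accession
effect), and broad-sense heritability H² = V_G/(V_G + V_R).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "ModelSpec",
    "CANDIDATE_SPECS",
    "enumerate_candidates",
    "VarianceComponents",
    "ModelFit",
    "HeritabilityResult",
    "ConvergenceError",
    "fit_vc_model",
    "select_model",
    "compute_blups",
    "compute_heritability",
    "fit_variable",
]

SPATIAL_TERMS = ("Block", "Column", "Row")


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class ModelSpec:
    """One candidate random-effects structure (Accession always included)."""

    structure_id: int
    random_terms: tuple[str, ...]

    def __post_init__(self):
        if self.random_terms[0] != "Accession":
            raise ValueError("Accession must be the first random term")
        if "Block" in self.random_terms and "Column" in self.random_terms:
            raise ValueError("Block and Column together overfit (columns are nested in blocks)")

    @property
    def label(self) -> str:
        return " + ".join(self.random_terms)


#: the six candidate structures, in canonical order
CANDIDATE_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec(1, ("Accession",)),
    ModelSpec(2, ("Accession", "Block")),
    ModelSpec(3, ("Accession", "Column")),
    ModelSpec(4, ("Accession", "Row")),
    ModelSpec(5, ("Accession", "Block", "Row")),
    ModelSpec(6, ("Accession", "Column", "Row")),
)


def enumerate_candidates() -> tuple[ModelSpec, ...]:
    """The six candidate model structures, in canonical order."""
    return CANDIDATE_SPECS


@dataclass
class VarianceComponents:
    """Estimated variances (trait units²); absent terms are None."""

    V_G: float
    V_R: float
    V_block: float | None = None
    V_column: float | None = None
    V_row: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"V_G": self.V_G, "V_R": self.V_R}
        for key, val in (("V_block", self.V_block), ("V_column", self.V_column), ("V_row", self.V_row)):
            if val is not None:
                out[key] = val
        return out


_TERM_TO_FIELD = {"Block": "V_block", "Column": "V_column", "Row": "V_row"}


@dataclass
class ModelFit:
    variable: str
    spec: ModelSpec
    intercept: float
    components: VarianceComponents
    ranef: dict[str, pd.Series]  # term -> predicted effects per level
    loglik: float  # restricted log-likelihood at the optimum
    aic: float
    n_obs: int
    n_params: int
    boundary_terms: tuple[str, ...] = ()
    converged: bool = True

    @property
    def accession_effects(self) -> pd.Series:
        return self.ranef["Accession"]


@dataclass
class HeritabilityResult:
    variable: str
    H2: float  # NaN when undefined
    structure_id: int
    defined: bool = True


def _design_matrix(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _factor(data: pd.DataFrame, term: str) -> pd.Categorical:
    if term == "Accession":
        return pd.Categorical(data["accession_id"])
    if term == "Block":
        return pd.Categorical(data["block"])
    if term == "Column":
        # columns are nested in blocks: the modelled factor is the
        # (block, column) pair, giving blocks x columns unique levels
        return pd.Categorical(list(zip(data["block"], data["column"])))
    if term == "Row":
        # row is a positional effect shared across blocks
        return pd.Categorical(data["row"])
    raise ValueError(f"unknown random term {term!r}")


def _neg2_reml_and_grad(
    gamma: np.ndarray,
    y: np.ndarray,
    Zs: list[np.ndarray],
    return_aux: bool = False,
):
    """Profiled −2·restricted-log-likelihood and its gradient in γ.

    H(γ) = I + Σ γ_k Z_k Z_kᵀ; σ²_R is profiled out in closed form.
    """
    n = y.size
    p = 1  # intercept only
    H = np.eye(n)
    for g, Z in zip(gamma, Zs):
        H += g * (Z @ Z.T)
    cho = linalg.cho_factor(H, lower=True, check_finite=False)
    logdet_H = 2.0 * np.log(np.diag(cho[0])).sum()
    X = np.ones((n, 1))
    HinvX = linalg.cho_solve(cho, X, check_finite=False)
    Hinvy = linalg.cho_solve(cho, y, check_finite=False)
    XtHinvX = float((X.T @ HinvX).item())
    beta = float(HinvX[:, 0] @ y) / XtHinvX
    Py = Hinvy - HinvX[:, 0] * beta  # P_H y
    quad = float(y @ Py)
    if quad <= 0:
        quad = np.finfo(float).tiny
    sigma2 = quad / (n - p)
    f = (
        (n - p) * np.log(sigma2)
        + logdet_H
        + np.log(XtHinvX)
        + (n - p)
        + (n - p) * np.log(2.0 * np.pi)
    )
    grad = np.empty_like(gamma)
    for k, Z in enumerate(Zs):
        HinvZ = linalg.cho_solve(cho, Z, check_finite=False)
        PZ = HinvZ - np.outer(HinvX[:, 0], (HinvX[:, 0] @ Z) / XtHinvX)
        tr_PA = float((Z * PZ).sum())
        ZtPy = Z.T @ Py
        grad[k] = tr_PA - (n - p) * float(ZtPy @ ZtPy) / quad
    if return_aux:
        return f, grad, dict(sigma2=sigma2, beta=beta, Py=Py, cho=cho)
    return f, grad


def fit_vc_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    value_col: str = "value",
    variable: str = "",
    tol: float = 1e-8,
) -> ModelFit:
    """Fit one random-effects structure by REML.

    Parameters
    ----------
    data
        Records with ``accession_id``, ``block``, ``column``, ``row`` and the
        value column; one row per plot observation.
    spec
        The candidate structure to fit.

    Raises
    ------
    ValueError
        Fewer than two accessions, or a random factor with a single level.
    ConvergenceError
        The optimizer did not converge from any starting point; carries the
        iteration trace.
    """
    y = data[value_col].to_numpy(dtype=float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        data = data.loc[keep]
        y = y[keep]
    n = y.size
    factors = {}
    Zs = []
    for term in spec.random_terms:
        cat = _factor(data, term)
        if len(cat.categories) < 2:
            raise ValueError(f"factor {term} has a single level; cannot estimate its variance")
        factors[term] = cat
        Zs.append(_design_matrix(cat.codes.astype(int), len(cat.categories)))
    if len(factors["Accession"].categories) < 2:
        raise ValueError("need at least two accessions")

    scale = y.std() or 1.0
    y_c = y / scale  # work on unit scale for optimizer conditioning

    trace: list = []

    def objective(g):
        f, grad = _neg2_reml_and_grad(g, y_c, Zs)
        trace.append((g.copy(), f))
        return f, grad

    k = len(Zs)
    starts = [np.ones(k), np.full(k, 0.1), np.full(k, 10.0)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * k,
            options={"ftol": tol * 1e-2, "gtol": 1e-10, "maxiter": 500},
        )
        if res.success and (best is None or res.fun < best.fun - 1e-12):
            best = res
        if best is not None and x0 is starts[0] and res.success:
            break  # default start converged; keep it (deterministic)
    if best is None:
        raise ConvergenceError(
            f"REML did not converge for structure {spec.label} ({len(trace)} evaluations)",
            trace=trace,
        )

    gamma = np.clip(best.x, 0.0, None)
    f, _, aux = _neg2_reml_and_grad(gamma, y_c, Zs, return_aux=True)
    sigma2 = aux["sigma2"] * scale**2
    intercept = aux["beta"] * scale
    # restricted loglik on the original scale: shifting y by scale c changes
    # -2l by (n-p)*log(c^2) (quad and sigma2 scale by c^2)
    loglik = -0.5 * (f + (n - 1) * np.log(scale**2))

    ranef: dict[str, pd.Series] = {}
    Py = aux["Py"]
    for term, Z, g in zip(spec.random_terms, Zs, gamma):
        u = g * (Z.T @ Py) * scale  # σ²_k Z' V⁻¹ r = γ_k Z' H⁻¹ r
        levels = factors[term].categories
        ranef[term] = pd.Series(u, index=levels, name=term)

    comp_kwargs = {"V_G": float(gamma[0] * sigma2), "V_R": float(sigma2)}
    boundary = []
    if gamma[0] == 0.0:
        boundary.append("Accession")
    for term, g in zip(spec.random_terms[1:], gamma[1:]):
        comp_kwargs[_TERM_TO_FIELD[term]] = float(g * sigma2)
        if g == 0.0:
            boundary.append(term)
    components = VarianceComponents(**comp_kwargs)

    # parameters: intercept + all variance components (incl. residual);
    # boundary estimates still count (simplest consistent convention)
    n_params = 1 + k + 1
    aic = -2.0 * loglik + 2.0 * n_params
    return ModelFit(
        variable=variable,
        spec=spec,
        intercept=float(intercept),
        components=components,
        ranef=ranef,
        loglik=float(loglik),
        aic=float(aic),
        n_obs=n,
        n_params=n_params,
        boundary_terms=tuple(boundary),
    )


def select_model(fits: Sequence[ModelFit]) -> ModelFit:
    """Pick the fit with the lowest AIC; ties go to fewer variance components."""
    fits = [f for f in fits if f is not None and f.converged]
    if not fits:
        raise ValueError("no converged fits to select from")
    return min(fits, key=lambda f: (f.aic, len(f.spec.random_terms), f.spec.structure_id))


def compute_blups(fit: ModelFit) -> pd.Series:
    """Per-accession BLUP values: intercept + predicted accession effect."""
    blups = fit.intercept + fit.accession_effects
    blups.name = fit.variable or "blup"
    return blups


def compute_heritability(fit: ModelFit) -> HeritabilityResult:
    """Broad-sense heritability H² = V_G/(V_G + V_R); NaN when both are zero."""
    vg, vr = fit.components.V_G, fit.components.V_R
    total = vg + vr
    if total <= 0:
        return HeritabilityResult(fit.variable, float("nan"), fit.spec.structure_id, defined=False)
    return HeritabilityResult(fit.variable, float(vg / total), fit.spec.structure_id)


def fit_variable(
    data: pd.DataFrame,
    variable: str = "",
    value_col: str = "value",
    candidates: Sequence[ModelSpec] = CANDIDATE_SPECS,
) -> tuple[ModelFit, list[ModelFit]]:
    """Fit every candidate structure and return (AIC-best, all converged fits).

    Candidates whose spatial factor degenerates (single level) or fails to
    converge are skipped; at least one candidate must survive.
    """
    fits: list[ModelFit] = []
    errors: list[str] = []
    for spec in candidates:
        try:
            fits.append(fit_vc_model(data, spec, value_col=value_col, variable=variable))
        except (ValueError, ConvergenceError, linalg.LinAlgError) as exc:
            errors.append(f"{spec.label}: {exc}")
    if not fits:
        raise ConvergenceError(
            "all candidate structures failed for "
            f"{variable or value_col}: " + "; ".join(errors)
        )
    return select_model(fits), fits
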