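"""Gibbs sampling for the geo-additive discrete-time logit hazard model.

The monthly hazard of child i in interval t is

    logit h_it = beta_0 + w_i' gamma + f_0(t) + f_age(a_i) + f_str(s_i) + f_unstr(s_i)

with f_0, f_age penalised B-spline smooths (second-order random-walk
priors), f_str an intrinsic-CAR field over provinces, f_unstr iid Normal
per province, diffuse Gaussian priors on the intercept and fixed effects,
and Inverse-Gamma(a, b) hyperpriors on every smoothing/spatial variance.

Inference uses Pólya-Gamma augmentation: given latent omega_it ~ PG(1,
eta_it) every coefficient block has an exact Gaussian full conditional, so
the sampler is a tuning-free Gibbs scheme.  Because covariates are constant
within a child and the baseline smooth depends only on t, all sufficient
statistics reduce to per-child and per-interval weighted sums; no dense
person-period matrix is ever formed.
"""

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .data_model import CATEGORY_LEVELS, MAX_AGE_MONTHS
from .polyagamma import polya_gamma
from .smoothers import SplineBasis
from .spatial import RegionGraph

__all__ = [
    "SmoothSpec",
    "SpatialSpec",
    "ModelSpec",
    "McmcConfig",
    "PosteriorSamples",
    "loglik",
    "fit",
    "update_variance",
    "update_block",
]

#: Non-reference indicator columns of the fully adjusted model, in reporting order.
DEFAULT_FIXED_TERMS = (
    ("residence", "rural"),
    ("sex", "male"),
    ("preceding_interval", "lt24"),
    ("antenatal", "none"),
    ("delivery_place", "home"),
    ("wealth", "low"),
    ("wealth", "middle"),
    ("education", "primary_or_less"),
    ("marital", "single"),
)


@dataclass(frozen=True)
class SmoothSpec:
    """Configuration of one penalised spline term."""

    field: str
    bounds: tuple
    n_inner_knots: int
    degree: int = 3
    a: float = 0.001  # Inverse-Gamma shape of the variance hyperprior
    b: float = 0.001  # Inverse-Gamma rate


@dataclass(frozen=True)
class SpatialSpec:
    a_str: float = 0.001
    b_str: float = 0.001
    a_unstr: float = 0.001
    b_unstr: float = 0.001


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: fixed terms (with references), smooths, spatial term."""

    fixed_terms: tuple = DEFAULT_FIXED_TERMS
    baseline: SmoothSpec | None = field(
        default_factory=lambda: SmoothSpec("t", (0.0, float(MAX_AGE_MONTHS)), 20)
    )
    mother_age: SmoothSpec | None = field(
        default_factory=lambda: SmoothSpec("mother_age_at_birth", (10.0, 50.0), 12)
    )
    spatial: SpatialSpec | None = field(default_factory=SpatialSpec)
    fixed_prior_precision: float = 1e-6

    def __post_init__(self):
        for fld, level in self.fixed_terms:
            if fld not in CATEGORY_LEVELS:
                raise ValueError(f"unknown covariate {fld!r} in fixed terms")
            if level not in CATEGORY_LEVELS[fld]:
                raise ValueError(f"unknown level {level!r} for covariate {fld!r}")
            if level == CATEGORY_LEVELS[fld][0]:
                raise ValueError(
                    f"{fld}:{level} is the reference level and cannot be a fixed term"
                )
        if not (self.fixed_prior_precision > 0):
            raise ValueError("fixed_prior_precision must be positive")

    @classmethod
    def default(cls):
        return cls()

    def without_smooths(self):
        return replace(self, baseline=None, mother_age=None)


@dataclass(frozen=True)
class McmcConfig:
    """Run-length settings; the seed is mandatory for reproducibility."""

    seed: int
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 10

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.seed is None:
            raise ValueError("an explicit seed is required")

    @property
    def n_draws(self):
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of every coefficient block and variance."""

    fixed_names: tuple
    intercept: np.ndarray  # (S,)
    gamma: np.ndarray  # (S, p)
    coef_baseline: np.ndarray | None  # (S, m0)
    coef_mother_age: np.ndarray | None  # (S, m_age)
    f_str: np.ndarray | None  # (S, R)
    f_unstr: np.ndarray | None  # (S, R)
    tau2: dict  # block name -> (S,)
    region_labels: tuple
    baseline_basis: SplineBasis | None
    mother_age_basis: SplineBasis | None
    model_spec: ModelSpec
    mcmc_config: McmcConfig

    @property
    def n_draws(self):
        return self.intercept.shape[0]

    def coefficient(self, term):
        """Draws of one fixed-effect log-odds coefficient by ``field:level``."""
        if term == "intercept":
            return self.intercept
        try:
            j = self.fixed_names.index(term)
        except ValueError:
            raise KeyError(f"unknown term label {term!r}; known: {self.fixed_names}")
        return self.gamma[:, j]

    def smooth_draws(self, term, grid):
        """Evaluate a centered smooth on ``grid`` for every retained draw."""
        if term in ("baseline", "t"):
            basis, coefs = self.baseline_basis, self.coef_baseline
        elif term in ("mother_age", "mother_age_at_birth"):
            basis, coefs = self.mother_age_basis, self.coef_mother_age
        else:
            raise KeyError(f"unknown smooth term {term!r}")
        if basis is None:
            raise KeyError(f"smooth term {term!r} was not part of the fitted model")
        return coefs @ basis.design(np.asarray(grid, float)).T

    def total_spatial(self):
        """Per-draw total residual spatial effect f_str + f_unstr, (S, R)."""
        if self.f_str is None:
            raise KeyError("the fitted model had no spatial term")
        return self.f_str + self.f_unstr

    def eta(self, person_periods, draw=None):
        """Linear predictor on a person-period table (posterior mean by default)."""
        sel = slice(None) if draw is None else slice(draw, draw + 1)

        def agg(x):
            return x[sel].mean(axis=0)

        eta = np.full(len(person_periods), agg(self.intercept))
        for j, name in enumerate(self.fixed_names):
            fld, level = name.split(":")
            eta += (person_periods[fld].to_numpy() == level) * agg(self.gamma[:, j])
        if self.baseline_basis is not None:
            b = self.baseline_basis.design(person_periods["t"].to_numpy(float))
            eta += b @ agg(self.coef_baseline)
        if self.mother_age_basis is not None:
            b = self.mother_age_basis.design(
                person_periods["mother_age_at_birth"].to_numpy(float)
            )
            eta += b @ agg(self.coef_mother_age)
        if self.f_str is not None:
            idx = {lab: i for i, lab in enumerate(self.region_labels)}
            prov = person_periods["province"].map(idx).to_numpy()
            eta += agg(self.f_str + self.f_unstr)[prov]
        return eta

    def save(self, out_dir):
        """Checkpoint all blocks as delimited text, one file per block."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        draw = np.arange(self.n_draws)
        pd.DataFrame({"draw": draw, "intercept": self.intercept}).to_csv(
            out / "samples_intercept.csv", index=False
        )
        pd.DataFrame(self.gamma, columns=list(self.fixed_names)).assign(draw=draw).to_csv(
            out / "samples_fixed.csv", index=False
        )
        if self.coef_baseline is not None:
            pd.DataFrame(self.coef_baseline).assign(draw=draw).to_csv(
                out / "samples_baseline_spline.csv", index=False
            )
        if self.coef_mother_age is not None:
            pd.DataFrame(self.coef_mother_age).assign(draw=draw).to_csv(
                out / "samples_mother_age_spline.csv", index=False
            )
        if self.f_str is not None:
            pd.DataFrame(self.f_str, columns=list(self.region_labels)).assign(
                draw=draw
            ).to_csv(out / "samples_spatial_structured.csv", index=False)
            pd.DataFrame(self.f_unstr, columns=list(self.region_labels)).assign(
                draw=draw
            ).to_csv(out / "samples_spatial_unstructured.csv", index=False)
        pd.DataFrame(self.tau2).assign(draw=draw).to_csv(
            out / "samples_variances.csv", index=False
        )


def loglik(eta, y):
    """Bernoulli-logit log-likelihood sum(y*eta - log(1 + exp(eta))), overflow-safe."""
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    if eta.shape != y.shape:
        raise ValueError(f"length mismatch: eta has shape {eta.shape}, y {y.shape}")
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def update_variance(f, K, a, b, rng, rank=None):
    """Conjugate Inverse-Gamma draw for a block variance.

    tau^2 | f ~ IG(a + rank(K)/2, b + f'Kf/2).
    """
    if a <= 0 or b <= 0:
        raise ValueError("hyperparameters a, b must be positive")
    K = np.asarray(K, dtype=float)
    f = np.asarray(f, dtype=float)
    if rank is None:
        rank = int(np.linalg.matrix_rank(K))
    shape = a + 0.5 * rank
    rate = b + 0.5 * float(f @ K @ f)
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def _draw_gaussian(precision, linear, rng, block="block"):
    """Exact draw from N(P^-1 b, P^-1) via Cholesky; raises naming the block."""
    try:
        c, low = cho_factor(precision, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"conditional precision for block {block!r} is not positive definite "
            f"(degenerate design, e.g. an empty covariate level?): {e}"
        )
    mean = cho_solve((c, low), linear)
    z = rng.standard_normal(len(linear))
    return mean + solve_triangular(c, z, lower=True, trans="T")


def update_block(design, kappa, omega, eta_rest, prior_precision, rng, block="block"):
    """Gaussian full-conditional draw for one coefficient block.

    Given Pólya-Gamma weights ``omega`` and working observations
    ``kappa = y - 1/2``, the block conditional is Normal with precision
    P = design' diag(omega) design + prior_precision and mean
    P^-1 design' (kappa - omega * eta_rest), where ``eta_rest`` is the
    linear predictor excluding this block.
    """
    design = np.asarray(design, dtype=float)
    omega = np.asarray(omega, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    eta_rest = np.asarray(eta_rest, dtype=float)
    P = design.T @ (design * omega[:, None]) + np.asarray(prior_precision, dtype=float)
    b = design.T @ (kappa - omega * eta_rest)
    return _draw_gaussian(P, b, rng, block=block)


def _indicator_matrix(frame, fixed_terms):
    names, cols = [], []
    for fld, level in fixed_terms:
        names.append(f"{fld}:{level}")
        cols.append((frame[fld].to_numpy() == level).astype(float))
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return tuple(names), X


def fit(person_periods, model_spec=None, graph=None, mcmc_config=None):
    """Run the augmented Gibbs sampler and return retained posterior draws.

    ``person_periods`` is the expanded child-month table from
    :func:`geosurv.data_model.expand`.  ``graph`` is required whenever the
    model has a spatial term.  Deterministic given the seed in
    ``mcmc_config``.
    """
    if model_spec is None:
        model_spec = ModelSpec.default()
    if mcmc_config is None:
        raise ValueError("an McmcConfig with an explicit seed is required")
    pp = person_periods
    n_pp = len(pp)
    if n_pp == 0:
        raise ValueError("empty person-period table")

    y = pp["y"].to_numpy(float)
    kappa_row = y - 0.5
    child_codes, child_idx = np.unique(pp["child_id"].to_numpy(), return_inverse=True)
    n_child = len(child_codes)
    first = np.zeros(n_child, dtype=int)
    first[child_idx[::-1]] = np.arange(n_pp - 1, -1, -1)
    child_frame = pp.iloc[first]

    fixed_names, Xf = _indicator_matrix(child_frame, model_spec.fixed_terms)
    # abort on empty levels rather than silently dropping a column
    for name, col in zip(fixed_names, Xf.T):
        if col.sum() == 0 or col.sum() == n_child:
            raise ValueError(
                f"fixed-effect block {name!r} has zero exposure in one level; "
                f"refit without this term or supply richer data"
            )
    Xc = np.column_stack([np.ones(n_child), Xf])  # intercept + indicators
    p_fixed = Xc.shape[1]

    t_row = pp["t"].to_numpy(int)
    if t_row.min() < 1:
        raise ValueError("person-period interval index t must start at 1")
    t_idx = t_row - 1
    n_t = int(t_row.max())

    baseline_basis = age_basis = None
    U_t = U_age = None
    K_t = K_age = None
    if model_spec.baseline is not None:
        s = model_spec.baseline
        baseline_basis = SplineBasis(s.bounds, s.n_inner_knots, s.degree)
        U_t = baseline_basis.design(np.arange(1, n_t + 1, dtype=float))
        K_t = baseline_basis.penalty
    if model_spec.mother_age is not None:
        s = model_spec.mother_age
        age_basis = SplineBasis(s.bounds, s.n_inner_knots, s.degree)
        U_age = age_basis.design(child_frame["mother_age_at_birth"].to_numpy(float))
        K_age = age_basis.penalty

    has_spatial = model_spec.spatial is not None
    if has_spatial:
        if graph is None or not isinstance(graph, RegionGraph):
            raise ValueError("a RegionGraph is required for the spatial term")
        region_labels = graph.labels
        idx_map = graph.index
        provs = child_frame["province"].to_numpy()
        unknown = sorted(set(provs) - set(region_labels))
        if unknown:
            raise ValueError(f"provinces not present in the region graph: {unknown}")
        prov_child = np.array([idx_map[s] for s in provs])
        R = graph.n_regions
        K_s = graph.precision()
        rank_s = R - graph.n_components()
    else:
        region_labels = ()
        prov_child = None
        R = 0

    cfg = mcmc_config
    rng = np.random.default_rng(cfg.seed)
    pg_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_iter)

    # state
    beta = np.zeros(p_fixed)
    a_t = np.zeros(U_t.shape[1]) if U_t is not None else None
    a_age = np.zeros(U_age.shape[1]) if U_age is not None else None
    f_str = np.zeros(R) if has_spatial else None
    f_unstr = np.zeros(R) if has_spatial else None
    tau2 = {"baseline": 0.1, "mother_age": 0.1, "spatial_str": 0.1, "spatial_unstr": 0.1}

    rows_per_child = np.bincount(child_idx, minlength=n_child).astype(float)
    rows_per_t = np.bincount(t_idx, minlength=n_t).astype(float)
    kappa_child = np.bincount(child_idx, weights=kappa_row, minlength=n_child)
    kappa_t = np.bincount(t_idx, weights=kappa_row, minlength=n_t)
    prior_fixed = model_spec.fixed_prior_precision * np.eye(p_fixed)

    def row_eta():
        e = Xc @ beta
        if U_age is not None:
            e = e + U_age @ a_age
        if has_spatial:
            e = e + (f_str + f_unstr)[prov_child]
        e = e[child_idx]
        if U_t is not None:
            e = e + (U_t @ a_t)[t_idx]
        return e

    eta = row_eta()

    S = cfg.n_draws
    out_intercept = np.empty(S)
    out_gamma = np.empty((S, p_fixed - 1))
    out_at = np.empty((S, a_t.size)) if a_t is not None else None
    out_aage = np.empty((S, a_age.size)) if a_age is not None else None
    out_fs = np.empty((S, R)) if has_spatial else None
    out_fu = np.empty((S, R)) if has_spatial else None
    out_tau = {
        k: np.empty(S)
        for k, use in (
            ("baseline", a_t is not None),
            ("mother_age", a_age is not None),
            ("spatial_str", has_spatial),
            ("spatial_unstr", has_spatial),
        )
        if use
    }

    rank_t = (K_t.shape[0] - 2) if K_t is not None else 0
    rank_age = (K_age.shape[0] - 2) if K_age is not None else 0

    keep = 0
    for it in range(cfg.n_iter):
        omega = polya_gamma(eta, pg_seeds[it])

        # --- fixed effects + intercept (child-level sufficient statistics)
        w_child = np.bincount(child_idx, weights=omega, minlength=n_child)
        wet_child = np.bincount(child_idx, weights=omega * eta, minlength=n_child)
        fitted = Xc @ beta
        eta_rest = np.divide(wet_child, w_child, out=np.zeros_like(wet_child),
                             where=w_child > 0) - fitted
        new = update_block(Xc, kappa_child, w_child, eta_rest, prior_fixed, rng,
                           block="fixed")
        eta += (Xc @ new - fitted)[child_idx]
        beta = new

        # --- baseline smooth (interval-level sufficient statistics)
        if a_t is not None:
            w_t = np.bincount(t_idx, weights=omega, minlength=n_t)
            wet_t = np.bincount(t_idx, weights=omega * eta, minlength=n_t)
            fitted = U_t @ a_t
            eta_rest = np.divide(wet_t, w_t, out=np.zeros_like(wet_t),
                                 where=w_t > 0) - fitted
            new = update_block(U_t, kappa_t, w_t, eta_rest, K_t / tau2["baseline"],
                               rng, block="baseline")
            # center over the observed t distribution; constant to intercept
            const = float((U_t @ new) @ rows_per_t / n_pp)
            new = new - const
            beta[0] += const
            eta += ((U_t @ new) - fitted)[t_idx] + const
            a_t = new

        # --- mother's-age smooth
        if a_age is not None:
            w_child = np.bincount(child_idx, weights=omega, minlength=n_child)
            wet_child = np.bincount(child_idx, weights=omega * eta, minlength=n_child)
            fitted = U_age @ a_age
            eta_rest = np.divide(wet_child, w_child, out=np.zeros_like(wet_child),
                                 where=w_child > 0) - fitted
            new = update_block(U_age, kappa_child, w_child, eta_rest,
                               K_age / tau2["mother_age"], rng, block="mother_age")
            const = float((U_age @ new) @ rows_per_child / n_pp)
            new = new - const
            beta[0] += const
            eta += ((U_age @ new) - fitted + const)[child_idx]
            a_age = new

        # --- spatial effects (province-level sufficient statistics)
        if has_spatial:
            w_child = np.bincount(child_idx, weights=omega, minlength=n_child)
            wet_child = np.bincount(child_idx, weights=omega * eta, minlength=n_child)
            w_prov = np.bincount(prov_child, weights=w_child, minlength=R)
            kap_prov = np.bincount(prov_child, weights=kappa_child, minlength=R)
            wet_prov = np.bincount(prov_child, weights=wet_child, minlength=R)
            for which in ("str", "unstr"):
                cur = f_str if which == "str" else f_unstr
                prior = (K_s / tau2["spatial_str"] if which == "str"
                         else np.eye(R) / tau2["spatial_unstr"])
                if which == "str":
                    # ICAR alone is improper on the constant; the data term
                    # plus centering keeps the draw well defined
                    prior = prior + 1e-10 * np.eye(R)
                eta_rest = np.divide(wet_prov, w_prov, out=np.zeros_like(wet_prov),
                                     where=w_prov > 0) - cur
                new = update_block(np.eye(R), kap_prov, w_prov, eta_rest, prior,
                                   rng, block=f"spatial_{which}")
                const = float(new.mean())
                new = new - const
                beta[0] += const
                delta = (new - cur)[prov_child] + const
                eta += delta[child_idx]
                wet_prov = wet_prov + w_prov * ((new - cur) + const)
                if which == "str":
                    f_str = new
                else:
                    f_unstr = new

        # --- variances
        if a_t is not None:
            tau2["baseline"] = max(
                update_variance(a_t, K_t, model_spec.baseline.a, model_spec.baseline.b,
                                rng, rank=rank_t), 1e-10)
        if a_age is not None:
            tau2["mother_age"] = max(
                update_variance(a_age, K_age, model_spec.mother_age.a,
                                model_spec.mother_age.b, rng, rank=rank_age), 1e-10)
        if has_spatial:
            sp = model_spec.spatial
            tau2["spatial_str"] = max(
                update_variance(f_str, K_s, sp.a_str, sp.b_str, rng, rank=rank_s),
                1e-10)
            tau2["spatial_unstr"] = max(
                update_variance(f_unstr, np.eye(R), sp.a_unstr, sp.b_unstr, rng,
                                rank=R), 1e-10)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            out_intercept[keep] = beta[0]
            out_gamma[keep] = beta[1:]
            if out_at is not None:
                out_at[keep] = a_t
            if out_aage is not None:
                out_aage[keep] = a_age
            if has_spatial:
                out_fs[keep] = f_str
                out_fu[keep] = f_unstr
            for k in out_tau:
                out_tau[k][keep] = tau2[k]
            keep += 1

    return PosteriorSamples(
        fixed_names=fixed_names,
        intercept=out_intercept[:keep],
        gamma=out_gamma[:keep],
        coef_baseline=out_at[:keep] if out_at is not None else None,
        coef_mother_age=out_aage[:keep] if out_aage is not None else None,
        f_str=out_fs[:keep] if has_spatial else None,
        f_unstr=out_fu[:keep] if has_spatial else None,
        tau2={k: v[:keep] for k, v in out_tau.items()},
        region_labels=region_labels,
        baseline_basis=baseline_basis,
        mother_age_basis=age_basis,
        model_spec=model_spec,
        mcmc_config=cfg,
    )
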