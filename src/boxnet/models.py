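"""Location-scale (distributional) response models.

The change in an individual's network statistic relative to the pre-event
baseline is modelled as a hierarchical Gaussian with linear predictors
for both the mean and the log residual spread:

    y_ij = x_ij' beta + u_i + e_ij,     u_i ~ N(0, tau^2),
    e_ij ~ N(0, sigma_ij^2),            log sigma_ij = z_ij' gamma.

``i`` indexes individuals (or communities), ``j`` repeated window
observations.  The default mean model is a full factorial of timestep
(categorical, reference level = first post-event window), standardized
pre-event sociality and standardized proportion of association strength
lost; the scale model is sociality x loss.  Estimation is by maximum
likelihood (marginal likelihood via a rank-one Woodbury identity per
group, analytic gradients, L-BFGS), with Wald 95% intervals from the
numerical Hessian.  ML point estimates coincide with flat-prior posterior
modes, so a sampling backend is an optional refinement rather than a
different model.

Observed effects are tested against the synchronized node-swap null by
refitting the model under each emitted permutation and computing add-one
empirical p-values per coefficient.  Because node swaps preserve every
network position's trajectory and only reassign identities, a randomized
refit is exactly a refit with the identity-linked attribute columns
permuted; :func:`permutation_effect_test` uses that fast route and
:func:`delta_table_from_stack` + :mod:`boxnet.permutation` provide the
explicit graph-relabelling route, which tests verify agrees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .permutation import SwapChain, empirical_pvalue

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model-ready tables


def standardize(x: pd.Series | np.ndarray) -> np.ndarray:
    """Mean-centre and scale to unit (population) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def build_response_table(
    delta: pd.DataFrame, attributes: pd.DataFrame
) -> pd.DataFrame:
    """Join change scores with pre-event attributes and standardize.

    ``delta`` is the output of :func:`boxnet.metrics.delta_from_baseline`;
    ``attributes`` the output of :func:`boxnet.networks.loss_attributes`
    (indexed by individual).  Rows whose loss proportion is undefined
    (zero pre-event strength) are dropped with a logged count.  Numeric
    predictors get standardized ``sociality_z`` / ``loss_z`` columns.
    """
    if not len(delta):
        raise ValueError("empty delta table")
    table = delta.merge(
        attributes.reset_index(), on="individual_id", how="left"
    )
    undefined = table["loss_proportion"].isna()
    if undefined.any():
        logger.info(
            "dropping %d rows with undefined loss proportion", int(undefined.sum())
        )
    table = table[~undefined].copy()
    if not len(table):
        raise ValueError("no rows with defined loss proportion")
    per_ind = table.drop_duplicates("individual_id")
    soc_z = dict(
        zip(per_ind["individual_id"], standardize(per_ind["pre_event_sociality"]))
    )
    loss_z = dict(zip(per_ind["individual_id"], standardize(per_ind["loss_proportion"])))
    table["sociality_z"] = table["individual_id"].map(soc_z)
    table["loss_z"] = table["individual_id"].map(loss_z)
    return table.reset_index(drop=True)


@dataclass(frozen=True)
class ModelSpec:
    """Which response and predictor structure to fit.

    ``variant``: ``"interaction"`` (timestep x sociality x loss full
    factorial), ``"additive"`` (timestep + sociality x loss), or
    ``"sex"`` (sex replacing sociality, full factorial).  The timestep
    reference level is the first post-event window.
    """

    response: str = "d_degree"
    variant: str = "interaction"
    scale_terms: tuple[str, ...] = ("sociality_z", "loss_z")
    group_col: str = "individual_id"

    def __post_init__(self) -> None:
        if self.variant not in ("interaction", "additive", "sex"):
            raise ValueError(f"unknown variant {self.variant!r}")


def _timestep_dummies(table: pd.DataFrame, reference: int) -> tuple[np.ndarray, list[str]]:
    levels = sorted(table["window"].unique())
    if reference not in levels:
        raise ValueError(f"reference window {reference} absent from table")
    others = [w for w in levels if w != reference]
    cols = [(table["window"] == w).to_numpy(dtype=float) for w in others]
    names = [f"t{w}" for w in others]
    return (np.column_stack(cols) if cols else np.empty((len(table), 0))), names


def design_matrices(
    table: pd.DataFrame, spec: ModelSpec, reference_window: int | None = None
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Build mean (X) and scale (Z) design matrices with term names.

    Treatment contrasts for timestep; numeric predictors are expected
    already standardized (``sociality_z``, ``loss_z``); ``sex`` is coded
    M=1 within the sex variant.
    """
    if reference_window is None:
        post = sorted(table.loc[table["phase"] == "post", "window"].unique())
        reference_window = post[0] if post else sorted(table["window"].unique())[0]
    T, t_names = _timestep_dummies(table, reference_window)
    if spec.variant == "sex":
        a = (table["sex"] == "M").to_numpy(dtype=float)
        a_name = "sexM"
    else:
        a = table["sociality_z"].to_numpy(dtype=float)
        a_name = "sociality_z"
    b = table["loss_z"].to_numpy(dtype=float)
    b_name = "loss_z"

    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]

    def add(col: np.ndarray, name: str) -> None:
        cols.append(col)
        names.append(name)

    for k, tn in enumerate(t_names):
        add(T[:, k], tn)
    add(a, a_name)
    add(b, b_name)
    add(a * b, f"{a_name}:{b_name}")
    if spec.variant in ("interaction", "sex"):
        for k, tn in enumerate(t_names):
            add(T[:, k] * a, f"{tn}:{a_name}")
        for k, tn in enumerate(t_names):
            add(T[:, k] * b, f"{tn}:{b_name}")
        for k, tn in enumerate(t_names):
            add(T[:, k] * a * b, f"{tn}:{a_name}:{b_name}")
    X = np.column_stack(cols)

    z_cols: list[np.ndarray] = [np.ones(n)]
    z_names: list[str] = ["scale_Intercept"]
    z_map = {"sociality_z": a if spec.variant != "sex" else table.get("sociality_z"),
             "loss_z": b, "sex": a}
    zs = []
    for term in spec.scale_terms:
        v = np.asarray(z_map[term], dtype=float)
        z_cols.append(v)
        z_names.append(f"scale_{term}")
        zs.append(v)
    if len(zs) == 2:
        z_cols.append(zs[0] * zs[1])
        z_names.append(f"scale_{spec.scale_terms[0]}:{spec.scale_terms[1]}")
    Z = np.column_stack(z_cols)
    return X, names, Z, z_names


# ---------------------------------------------------------------------------
# the model


class LocationScaleModel:
    """Hierarchical Gaussian model with mean and log-scale predictors.

    Parameters
    ----------
    endog : array
        Response vector.
    exog_mean : array
        Mean-model design matrix X (include the intercept column).
    exog_scale : array
        Scale-model design matrix Z for ``log sigma`` (include intercept).
    groups : array or None
        Group labels for the random intercept; ``None`` fits without a
        random effect.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog_mean: np.ndarray,
        exog_scale: np.ndarray | None = None,
        groups: np.ndarray | None = None,
        mean_names: Sequence[str] | None = None,
        scale_names: Sequence[str] | None = None,
    ):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.atleast_2d(np.asarray(exog_mean, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            self.X = self.X.T
        self.Z = (
            np.ones((len(self.y), 1))
            if exog_scale is None
            else np.atleast_2d(np.asarray(exog_scale, dtype=float))
        )
        if self.Z.shape[0] != self.y.shape[0]:
            self.Z = self.Z.T
        self.mean_names = list(mean_names or [f"x{i}" for i in range(self.X.shape[1])])
        self.scale_names = list(scale_names or [f"scale_z{i}" for i in range(self.Z.shape[1])])
        if groups is None:
            self.group_idx = None
            self.n_groups = 0
        else:
            codes, _ = pd.factorize(np.asarray(groups))
            self.group_idx = codes
            self.n_groups = int(codes.max()) + 1
        self.p = self.X.shape[1]
        self.q = self.Z.shape[1]
        self.n_params = self.p + self.q + (1 if self.group_idx is not None else 0)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        spec: ModelSpec | None = None,
        reference_window: int | None = None,
    ) -> "LocationScaleModel":
        """Build the model from a response table (see
        :func:`build_response_table`) and a :class:`ModelSpec`."""
        spec = spec or ModelSpec()
        X, names, Z, z_names = design_matrices(table, spec, reference_window)
        groups = table[spec.group_col].to_numpy() if spec.group_col else None
        return cls(
            table[spec.response].to_numpy(dtype=float),
            X,
            Z,
            groups,
            mean_names=names,
            scale_names=z_names,
        )

    # -- likelihood --------------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        beta = theta[: self.p]
        gamma = theta[self.p : self.p + self.q]
        log_tau = theta[-1] if self.group_idx is not None else None
        return beta, gamma, log_tau

    def loglike(self, theta: np.ndarray) -> float:
        return -self._nll_grad(theta)[0]

    def _nll_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative marginal log-likelihood and its analytic gradient."""
        beta, gamma, log_tau = self._unpack(theta)
        y, X, Z = self.y, self.X, self.Z
        n = len(y)
        eta = np.clip(Z @ gamma, -30.0, 30.0)
        sig2 = np.exp(2.0 * eta)
        u = 1.0 / sig2                       # precisions
        r = y - X @ beta

        if self.group_idx is None:
            nll = 0.5 * (n * np.log(2 * np.pi) + 2.0 * eta.sum() + np.sum(u * r * r))
            w = u * r
            g_beta = -X.T @ w
            h = 1.0 - u * r * r
            g_gamma = Z.T @ h
            return float(nll), np.concatenate([g_beta, g_gamma])

        tau2 = np.exp(2.0 * np.clip(log_tau, -30.0, 15.0))
        idx = self.group_idx
        a = np.bincount(idx, weights=u, minlength=self.n_groups)
        m = np.bincount(idx, weights=u * r, minlength=self.n_groups)
        c = tau2 / (1.0 + tau2 * a)

        nll = 0.5 * (
            n * np.log(2 * np.pi)
            + 2.0 * eta.sum()
            + np.sum(np.log1p(tau2 * a))
            + np.sum(u * r * r)
            - np.sum(c * m * m)
        )
        # gradients
        w = u * r - c[idx] * m[idx] * u       # = V^{-1} r elementwise
        g_beta = -X.T @ w
        h = 1.0 - u * (c[idx] + (r - c[idx] * m[idx]) ** 2)
        g_gamma = Z.T @ h
        g_tau = float(np.sum(c * (a - (1.0 - c * a) * m * m)))
        return float(nll), np.concatenate([g_beta, g_gamma, [g_tau]])

    # -- fitting -----------------------------------------------------------

    def _start(self) -> np.ndarray:
        XtX = self.X.T @ self.X
        beta0 = np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        resid = self.y - self.X @ beta0
        s = max(resid.std(), 1e-3)
        gamma0 = np.zeros(self.q)
        gamma0[0] = np.log(s)
        if self.group_idx is None:
            return np.concatenate([beta0, gamma0])
        return np.concatenate([beta0, gamma0, [np.log(s) - np.log(2.0)]])

    def fit(
        self,
        maxiter: int = 2000,
        se: bool = True,
        start: np.ndarray | None = None,
    ) -> "LocationScaleResults":
        """Maximize the marginal likelihood; returns a results object.

        ``start`` overrides the default least-squares starting values
        (useful to warm-start many related fits); ``se=False`` skips the
        numerical Hessian.
        """
        theta0 = self._start() if start is None else np.asarray(start, dtype=float)
        # log-scale parameters are box-bounded: the ML objective diverges
        # as any sigma -> 0 when the mean model saturates, and the bounds
        # (sigma, tau within e**±12 of 1) keep such degenerate fits finite
        # without constraining any realistic interior optimum
        bounds = [(None, None)] * self.p + [(-12.0, 12.0)] * (
            self.n_params - self.p
        )
        res = optimize.minimize(
            self._nll_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"location-scale fit did not converge: {res.message}",
                RuntimeWarning,
                stacklevel=2,
            )
        bse = np.full(self.n_params, np.nan)
        if se:
            try:
                hess = _numerical_hessian(lambda t: self._nll_grad(t)[1], res.x)
                cov = np.linalg.inv(hess)
                diag = np.diag(cov)
                bse = np.sqrt(np.where(diag > 0, diag, np.nan))
            except np.linalg.LinAlgError:
                converged = False
        return LocationScaleResults(self, res.x, bse, -res.fun, converged)


def _numerical_hessian(grad: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                       eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        H[:, i] = (grad(xp) - grad(xm)) / (2 * step)
    return (H + H.T) / 2


@dataclass
class LocationScaleResults:
    """Fitted location-scale model: estimates, uncertainty, diagnostics."""

    model: LocationScaleModel
    theta: np.ndarray
    bse_all: np.ndarray
    llf: float
    converged: bool
    empirical_pvalues: dict[str, float] | None = None

    @property
    def params(self) -> pd.Series:
        """Mean-model coefficients beta."""
        return pd.Series(self.theta[: self.model.p], index=self.model.mean_names)

    @property
    def scale_params(self) -> pd.Series:
        """Scale-model coefficients gamma (log residual sd)."""
        return pd.Series(
            self.theta[self.model.p : self.model.p + self.model.q],
            index=self.model.scale_names,
        )

    @property
    def tau(self) -> float:
        """Random-intercept standard deviation."""
        if self.model.group_idx is None:
            return 0.0
        return float(np.exp(self.theta[-1]))

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.bse_all[: self.model.p], index=self.model.mean_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals for all parameters (mean, scale, log tau)."""
        z = stats.norm.ppf(1 - alpha / 2)
        names = self.model.mean_names + self.model.scale_names + (
            ["log_tau"] if self.model.group_idx is not None else []
        )
        est = self.theta
        return pd.DataFrame(
            {"lower": est - z * self.bse_all, "estimate": est,
             "upper": est + z * self.bse_all},
            index=names,
        )

    def coefficient_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        tab = ci[["estimate", "lower", "upper"]].copy()
        tab.insert(1, "se", self.bse_all)
        if self.empirical_pvalues:
            tab["empirical_p"] = pd.Series(self.empirical_pvalues)
        return tab

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.theta[: self.model.p]

    def summary(self) -> str:
        lines = [
            "Location-scale hierarchical Gaussian model (ML)",
            f"  observations: {len(self.model.y)}"
            + (
                f", groups: {self.model.n_groups}, tau = {self.tau:.4f}"
                if self.model.group_idx is not None
                else ""
            ),
            f"  log-likelihood: {self.llf:.3f}   converged: {self.converged}",
            "",
            self.coefficient_table().round(4).to_string(),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operations on stacks and tables


def fit_location_scale(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> LocationScaleResults:
    """Fit the location-scale model defined by ``spec`` on a response table."""
    return LocationScaleModel.from_dataframe(table, spec).fit()


def _permute_attribute_columns(
    table: pd.DataFrame, permutation: Mapping[str, str]
) -> pd.DataFrame:
    """Reassign identity-linked attributes according to a node-swap state.

    Under the swap ``identity -> position``, identity ``i``'s network
    trajectory (response rows) becomes position ``perm[i]``'s observed
    one; equivalently each observed row of individual ``pos`` carries the
    attributes of the identity now occupying ``pos``.
    """
    inverse = {pos: ident for ident, pos in permutation.items()}
    attr_cols = [c for c in ("sociality_z", "loss_z", "pre_event_sociality",
                             "loss_proportion", "sex") if c in table.columns]
    per_ind = table.drop_duplicates("individual_id").set_index("individual_id")
    out = table.copy()
    owners = table["individual_id"].map(lambda p: inverse.get(p, p))
    for c in attr_cols:
        out[c] = owners.map(per_ind[c]).to_numpy()
    return out


def permutation_effect_test(
    table: pd.DataFrame,
    spec: ModelSpec,
    chain: SwapChain,
    n_emissions: int | None = None,
    fit_kwargs: Mapping | None = None,
) -> tuple[LocationScaleResults, pd.DataFrame]:
    """Empirical per-coefficient p-values against the node-swap null.

    Fits the observed model, then refits under each of the chain's
    emissions (identities permuted, positions' responses unchanged) and
    computes two-sided add-one empirical p-values for every mean- and
    scale-model coefficient.  Non-converged randomized fits are dropped
    with a logged count; all failing is an error.

    Returns the observed results (with ``empirical_pvalues`` attached)
    and the R x n_coefficients frame of randomized estimates.
    """
    missing = set(chain.pool) - set(table["individual_id"])
    if missing:
        raise ValueError("chain pool contains identities absent from the table")
    observed = fit_location_scale(table, spec)
    names = observed.model.mean_names + observed.model.scale_names
    draws = []
    dropped = 0
    for r, perm in chain.permutations():
        if n_emissions is not None and r >= n_emissions:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model_r = LocationScaleModel.from_dataframe(
                _permute_attribute_columns(table, perm), spec
            )
            # randomized fits need point estimates only; warm-start at the
            # observed optimum (same topology, permuted attributes)
            fit = model_r.fit(se=False, start=observed.theta,
                              **(dict(fit_kwargs) if fit_kwargs else {}))
        if not fit.converged:
            dropped += 1
            continue
        draws.append(np.concatenate([fit.params.to_numpy(), fit.scale_params.to_numpy()]))
    if not draws:
        raise RuntimeError("all randomized fits failed to converge")
    if dropped:
        logger.info("dropped %d non-converged randomized fits", dropped)
    rand = pd.DataFrame(draws, columns=names)
    obs_vec = np.concatenate([observed.params.to_numpy(), observed.scale_params.to_numpy()])
    observed.empirical_pvalues = {
        name: empirical_pvalue(obs_vec[k], rand[name].to_numpy())
        for k, name in enumerate(names)
    }
    return observed, rand


def build_community_table(
    stats_by_window: Mapping[int, pd.DataFrame],
    baseline_window: int,
    post_windows: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Model-ready table of community change scores.

    ``stats_by_window`` maps window index to a group-stats frame (see
    :func:`boxnet.metrics.group_stats`) keyed on persistent community
    ids.  Responses are the change in size and within-community density
    relative to the baseline window; predictors are standardized
    pre-event size and proportion missing (taken from the baseline row).
    """
    base = stats_by_window[baseline_window].set_index("community")
    rows = []
    for w, df in stats_by_window.items():
        if w == baseline_window:
            continue
        for row in df.itertuples(index=False):
            if row.community not in base.index:
                continue
            b = base.loc[row.community]
            rows.append(
                {
                    "community": row.community,
                    "window": w,
                    "phase": "post" if post_windows is None or w in post_windows else "pre",
                    "d_size": row.size - b["size"],
                    "d_density": row.within_density - b["within_density"],
                    "pre_size": b["size"],
                    "prop_missing": b["prop_missing"],
                }
            )
    table = pd.DataFrame(rows)
    if not len(table):
        raise ValueError("no communities shared with the baseline window")
    per_comm = table.drop_duplicates("community")
    size_z = dict(zip(per_comm["community"], standardize(per_comm["pre_size"])))
    miss_z = dict(zip(per_comm["community"], standardize(per_comm["prop_missing"])))
    table["sociality_z"] = table["community"].map(size_z)   # pre-event size slot
    table["loss_z"] = table["community"].map(miss_z)        # proportion-missing slot
    table = table.rename(columns={"community": "individual_id"})
    return table.reset_index(drop=True)


def fit_community_model(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> LocationScaleResults:
    """Community-level change model (random intercept per community).

    Uses the same location-scale machinery on a table from
    :func:`build_community_table` (``sociality_z`` carries standardized
    pre-event community size, ``loss_z`` standardized proportion
    missing).  With a single community the random effect is degenerate
    and the model falls back to no grouping with a warning.
    """
    spec = spec or ModelSpec(response="d_size")
    if table["individual_id"].nunique() < 2:
        warnings.warn(
            "single community: fitting without a random effect", RuntimeWarning,
            stacklevel=2,
        )
        X, names, Z, z_names = design_matrices(table, spec)
        model = LocationScaleModel(
            table[spec.response].to_numpy(dtype=float), X, Z, None, names, z_names
        )
        return model.fit()
    return fit_location_scale(table, spec)
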