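"""Per-subject, per-condition parameter estimation (constrained MLE / MAP).

Each condition stream (or a valence's mixed + separate stream pair, for the
context-scheme variants) is fit by minimizing the trial-replay negative
log-likelihood over bounded parameters with L-BFGS-B, using the analytic
gradient propagated through the value-update recursion. MAP estimation adds
weakly informative priors -- Beta(1.1, 1.1) on each learning rate and
Gamma(shape 15, scale 0.75) on the inverse temperature -- to the objective.
Optimization restarts from ``n_starts`` prior-drawn points (the first start
sits at the prior modes) and keeps the best.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import pearsonr

from .rl import ModelSpec, Stream, compile_stream, replay_nll_arrays
from .synth import DEFAULT_PRIOR, PriorSpec
from .task import CONDITIONS

_EPS = 1e-9


@dataclass(frozen=True)
class FitConfig:
    estimator: str = "mle"                  # "mle" or "map"
    n_starts: int = 10
    alpha_bounds: tuple = (0.0, 1.0)
    beta_bounds: tuple = (0.0, 50.0)
    rho_bounds: tuple = (0.0, 3.0)
    prior: PriorSpec = DEFAULT_PRIOR
    fixed: dict = field(default_factory=dict)
    min_trials: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.estimator not in ("mle", "map"):
            raise ValueError("estimator must be 'mle' or 'map'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    params: dict
    nll: float
    objective: float
    log_posterior: float | None
    n_valid_trials: int
    k: int
    converged: bool
    best_start: int
    estimator: str

    def agent_params(self, q0_scheme="signed_half", q0_free=None):
        """Best-fit values as :class:`~contextrl.rl.AgentParams` (base models)."""
        from .rl import AgentParams

        p = self.params
        a_pos = p.get("alpha_pos", p.get("alpha"))
        a_neg = p.get("alpha_neg", p.get("alpha"))
        return AgentParams(a_pos, a_neg, p["beta"], p.get("rho", 1.0),
                           q0_scheme=q0_scheme, q0_free=q0_free)


# --- parameter layout --------------------------------------------------------

class _Layout:
    """Free-parameter naming, bounds, and stream wiring for a ModelSpec."""

    def __init__(self, model_spec: ModelSpec, streams: dict, config: FitConfig):
        ms = model_spec
        self.names: list[str] = []
        self.kinds: list[str] = []
        if ms.context_scheme is None:
            if len(streams) != 1:
                raise ValueError("base models fit exactly one stream")
            if ms.n_alphas == 2:
                self._add("alpha_pos", "alpha")
                self._add("alpha_neg", "alpha")
            else:
                self._add("alpha", "alpha")
            self._add("beta", "beta")
            if ms.sensitivity:
                self._add("rho", "rho")
            key = next(iter(streams))
            if ms.n_alphas == 2:
                wiring = {key: ("alpha_pos", "alpha_neg", "beta",
                                "rho" if ms.sensitivity else None)}
            else:
                wiring = {key: ("alpha", "alpha", "beta",
                                "rho" if ms.sensitivity else None)}
        else:
            if set(streams) != {"mixed", "only"}:
                raise ValueError("context-scheme fits need 'mixed' and 'only' streams")
            scheme = ms.context_scheme
            if scheme == "null":
                for n in ("alpha", "beta"):
                    self._add(n, n.split("_")[0])
                wiring = {c: ("alpha", "alpha", "beta", None) for c in ("mixed", "only")}
            elif scheme == "alpha_only":
                self._add("alpha_mixed", "alpha")
                self._add("alpha_only", "alpha")
                self._add("beta", "beta")
                wiring = {c: (f"alpha_{c}", f"alpha_{c}", "beta", None)
                          for c in ("mixed", "only")}
            elif scheme == "beta_only":
                self._add("alpha", "alpha")
                self._add("beta_mixed", "beta")
                self._add("beta_only", "beta")
                wiring = {c: ("alpha", "alpha", f"beta_{c}", None)
                          for c in ("mixed", "only")}
            else:  # full
                for c in ("mixed", "only"):
                    self._add(f"alpha_{c}", "alpha")
                for c in ("mixed", "only"):
                    self._add(f"beta_{c}", "beta")
                wiring = {c: (f"alpha_{c}", f"alpha_{c}", f"beta_{c}", None)
                          for c in ("mixed", "only")}
        self.wiring = wiring
        unknown = set(config.fixed) - set(self.names)
        if unknown:
            raise ValueError(f"fixed parameters not in model: {unknown}")
        self.free = [n for n in self.names if n not in config.fixed]
        self.fixed = dict(config.fixed)
        bmap = {"alpha": config.alpha_bounds, "beta": config.beta_bounds,
                "rho": config.rho_bounds}
        self.bounds = [bmap[self.kinds[self.names.index(n)]] for n in self.free]

    def _add(self, name, kind):
        self.names.append(name)
        self.kinds.append(kind)

    def kind_of(self, name):
        return self.kinds[self.names.index(name)]

    def full_values(self, x) -> dict:
        vals = dict(zip(self.free, x))
        vals.update(self.fixed)
        return vals


# --- priors ------------------------------------------------------------------

def _log_prior_and_grad(vals: dict, layout: _Layout, prior: PriorSpec):
    """Sum of log prior densities over alpha- and beta-kind parameters."""
    a, b = prior.alpha_a, prior.alpha_b
    lb_const = gammaln(a + b) - gammaln(a) - gammaln(b)
    k, th = prior.beta_shape, prior.beta_scale
    lg_const = -gammaln(k) - k * np.log(th)
    lp = 0.0
    grad = {}
    for name, v in vals.items():
        kind = layout.kind_of(name)
        if kind == "alpha":
            x = min(max(v, _EPS), 1 - _EPS)
            lp += lb_const + (a - 1) * np.log(x) + (b - 1) * np.log(1 - x)
            grad[name] = (a - 1) / x - (b - 1) / (1 - x)
        elif kind == "beta":
            x = max(v, _EPS)
            lp += lg_const + (k - 1) * np.log(x) - x / th
            grad[name] = (k - 1) / x - 1.0 / th
        else:
            grad[name] = 0.0
    return lp, grad


# --- core fit ----------------------------------------------------------------

def _as_streams(streams) -> dict:
    if isinstance(streams, dict):
        return {k: (v if isinstance(v, Stream) else compile_stream(v))
                for k, v in streams.items()}
    s = streams if isinstance(streams, Stream) else compile_stream(streams)
    return {"stream": s}


def _make_objective(compiled: dict, layout: _Layout, model_spec: ModelSpec,
                    config: FitConfig):
    q0s = {key: s.q0(model_spec.q0_scheme, model_spec.q0_free)
           for key, s in compiled.items()}
    use_map = config.estimator == "map"

    def objective(x):
        vals = layout.full_values(x)
        nll = 0.0
        g = dict.fromkeys(layout.names, 0.0)
        for key, s in compiled.items():
            a_pos_n, a_neg_n, beta_n, rho_n = layout.wiring[key]
            rho = vals[rho_n] if rho_n is not None else 1.0
            ll, _, kg = replay_nll_arrays(
                s, vals[a_pos_n], vals[a_neg_n], vals[beta_n], rho, q0=q0s[key]
            )
            nll += ll
            g[a_pos_n] += kg[0]
            g[a_neg_n] += kg[1]
            g[beta_n] += kg[2]
            if rho_n is not None:
                g[rho_n] += kg[3]
        f = nll
        if use_map:
            lp, pg = _log_prior_and_grad(vals, layout, config.prior)
            f = nll - lp
            for name in g:
                g[name] -= pg.get(name, 0.0)
        return f, np.array([g[n] for n in layout.free]), nll

    return objective


def _starts(layout: _Layout, config: FitConfig, rng: np.random.Generator):
    a_mode, b_mode = config.prior.modes()
    mode = {"alpha": np.clip(a_mode, *config.alpha_bounds),
            "beta": np.clip(b_mode, *config.beta_bounds),
            "rho": 1.0}
    pts = [np.array([mode[layout.kind_of(n)] for n in layout.free])]
    for _ in range(config.n_starts - 1):
        pt = []
        for n in layout.free:
            kind = layout.kind_of(n)
            if kind == "alpha":
                v = rng.beta(config.prior.alpha_a, config.prior.alpha_b)
                v = np.clip(v, *config.alpha_bounds)
            elif kind == "beta":
                v = np.clip(rng.gamma(config.prior.beta_shape, config.prior.beta_scale),
                            *config.beta_bounds)
            else:
                v = rng.uniform(*config.rho_bounds)
            pt.append(v)
        pts.append(np.array(pt))
    return pts


def fit_condition(streams, model_spec: ModelSpec | None = None,
                  config: FitConfig | None = None) -> FitResult:
    """Fit one condition stream (or a mixed/only pair) and return the best fit.

    ``streams`` is a trial DataFrame (or compiled :class:`Stream`) for base
    models, or a dict ``{"mixed": ..., "only": ...}`` for the
    context-scheme variants. With no valid trials, a MAP fit returns the
    prior modes; an MLE fit raises. If no start converges the best point is
    still returned with ``converged=False``.
    """
    model_spec = model_spec or ModelSpec()
    config = config or FitConfig()
    compiled = _as_streams(streams)
    layout = _Layout(model_spec, compiled, config)
    n_valid = sum(s.n_trials for s in compiled.values())
    k = len(layout.free)

    if n_valid == 0:
        if config.estimator != "map":
            raise ValueError("no valid trials and no prior to fall back on")
        a_mode, b_mode = config.prior.modes()
        vals = {n: (a_mode if layout.kind_of(n) == "alpha"
                    else b_mode if layout.kind_of(n) == "beta" else 1.0)
                for n in layout.free}
        vals.update(layout.fixed)
        lp, _ = _log_prior_and_grad(vals, layout, config.prior)
        return FitResult(vals, 0.0, -lp, lp, 0, k, True, 0, config.estimator)
    if n_valid < config.min_trials:
        raise ValueError(
            f"only {n_valid} valid trials (< min_trials={config.min_trials})")

    objective = _make_objective(compiled, layout, model_spec, config)

    def fg(x):
        f, g, _ = objective(x)
        return f, g

    rng = np.random.default_rng(config.seed)
    best = None
    best_start = -1
    any_success = False
    for i, x0 in enumerate(_starts(layout, config, rng)):
        res = minimize(fg, x0, jac=True, method="L-BFGS-B", bounds=layout.bounds)
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best, best_start = res, i
    vals = layout.full_values(best.x)
    _, _, nll = objective(best.x)
    at_beta_bound = any(
        layout.kind_of(n) == "beta"
        and abs(vals[n] - config.beta_bounds[1]) < 1e-6
        for n in layout.free
    )
    converged = bool(any_success and not at_beta_bound)
    log_post = -best.fun if config.estimator == "map" else None
    return FitResult(vals, float(nll), float(best.fun), log_post,
                     n_valid, k, converged, best_start, config.estimator)


# --- cohort-level helpers ----------------------------------------------------

def fit_dataset(dataset: pd.DataFrame, model_spec: ModelSpec | None = None,
                config: FitConfig | None = None) -> pd.DataFrame:
    """Fit every subject x condition of a dataset; one tidy row per fit."""
    model_spec = model_spec or ModelSpec()
    config = config or FitConfig()
    rows = []
    for (subject, cond), grp in dataset.groupby(["subject", "condition"], sort=True):
        res = fit_condition(grp, model_spec, config)
        row = {"subject": subject, "condition": cond, **res.params,
               "nll": res.nll, "n": res.n_valid_trials, "k": res.k,
               "converged": res.converged}
        rows.append(row)
    return pd.DataFrame(rows)


def fit_variants_by_valence(dataset: pd.DataFrame, valence: str, schemes,
                            config: FitConfig | None = None) -> pd.DataFrame:
    """Fit context-scheme variants jointly over a valence's two streams."""
    config = config or FitConfig()
    rows = []
    for subject, grp in dataset[dataset["valence"] == valence].groupby("subject"):
        streams = {
            "mixed": grp[grp["context"] == "mixed"],
            "only": grp[grp["context"] != "mixed"],
        }
        for scheme in schemes:
            ms = ModelSpec(n_alphas=1, context_scheme=scheme)
            res = fit_condition(streams, ms, config)
            rows.append({"subject": subject, "valence": valence, "scheme": scheme,
                         "nll": res.nll, "n": res.n_valid_trials, "k": res.k,
                         "converged": res.converged, **res.params})
    return pd.DataFrame(rows)


def grid_oracle(streams, model_spec: ModelSpec | None = None,
                grid_spec: dict | None = None,
                max_evals: int = 10**6):
    """Exhaustive nll minimum over a parameter grid (optimizer cross-check).

    ``grid_spec`` maps free-parameter names to value arrays. Returns
    ``(best_params, best_nll)``.
    """
    model_spec = model_spec or ModelSpec()
    config = FitConfig(estimator="mle")
    compiled = _as_streams(streams)
    layout = _Layout(model_spec, compiled, config)
    if grid_spec is None or any(len(v) == 0 for v in grid_spec.values()):
        raise ValueError("empty grid")
    if set(grid_spec) != set(layout.free):
        raise ValueError(f"grid must cover exactly {layout.free}")
    sizes = int(np.prod([len(grid_spec[n]) for n in layout.free]))
    if sizes > max_evals:
        raise ValueError(f"grid has {sizes} points (> {max_evals})")
    objective = _make_objective(compiled, layout, model_spec, config)
    best_nll, best_x = np.inf, None
    for point in itertools.product(*(grid_spec[n] for n in layout.free)):
        f, _, _ = objective(np.array(point, dtype=float))
        if f < best_nll:
            best_nll, best_x = f, point
    return layout.full_values(np.array(best_x)), float(best_nll)


def compare_mle_map_pes(dataset: pd.DataFrame, model_spec: ModelSpec | None = None,
                        config: FitConfig | None = None) -> pd.Series:
    """Pearson r between MLE- and MAP-derived trialwise PEs, per condition.

    Both estimators are run on identical streams; the fitted models are
    replayed to get each valid trial's signed PE and the two PE vectors are
    correlated within each condition (pooled over subjects).
    """
    model_spec = model_spec or ModelSpec()
    config = config or FitConfig()
    pes = {cond: {"mle": [], "map": []} for cond in CONDITIONS}
    for (subject, cond), grp in dataset.groupby(["subject", "condition"], sort=True):
        stream = compile_stream(grp)
        if stream.n_trials < 3:
            raise ValueError(f"subject {subject} {cond}: fewer than 3 valid trials")
        for est in ("mle", "map"):
            res = fit_condition(stream, model_spec, replace(config, estimator=est))
            p = res.agent_params(model_spec.q0_scheme, model_spec.q0_free)
            _, pe, _ = replay_nll_arrays(
                stream, p.alpha_pos, p.alpha_neg, p.beta, p.rho,
                q0_scheme=model_spec.q0_scheme, q0_free=model_spec.q0_free)
            pes[cond][est].append(pe)
    out = {}
    for cond, d in pes.items():
        if not d["mle"]:
            continue
        a = np.concatenate(d["mle"])
        b = np.concatenate(d["map"])
        out[cond] = float(pearsonr(a, b).statistic)
    return pd.Series(out, name="pe_correlation")
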