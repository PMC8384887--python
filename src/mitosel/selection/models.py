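"""Codon model fitting: M0, free-ratios, branch, M2a_rel, CmC, branch-site A.

Every model is expressed as a *layout*: a vector of distinct omega
values, an index matrix ``omega_idx[node, class]`` and mixture weights.
The optimizer works on transformed coordinates (log for kappa and the
omegas, stick-breaking logits for proportions) with bounded L-BFGS-B and
seeded multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .alignment import CodonAlignment
from .likelihood import PruningEngine
from .qmatrix import f3x4_frequencies
from .trees import LabeledTree

MODELS = (
    "M0",
    "free_ratios",
    "branch",
    "M2a_rel",
    "CmC",
    "BSM_A",
    "BSM_A_null",
)

KAPPA_BOUNDS = (0.1, 99.0)
OMEGA_BOUNDS = (1e-4, 50.0)
LOGIT_BOUND = 8.0


@dataclass
class CodonModelFit:
    """Fitted codon model: parameters, likelihood and convergence metadata."""

    model: str
    lnl: float
    kappa: float
    params: dict
    n_free_params: int
    converged: bool
    n_evaluations: int
    n_starts: int
    theta: np.ndarray = field(repr=False)
    group_names: list[str] = field(default_factory=list)

    @property
    def omega_summary(self) -> dict:
        """Per-branch-group or per-class omega view, model dependent."""
        return {
            k: v
            for k, v in self.params.items()
            if k.startswith("omega") or k in ("p0", "p1", "p2")
        }


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


class _ModelSpec:
    """Maps a flat transformed parameter vector to a likelihood layout."""

    def __init__(self, model: str, tree: LabeledTree):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        self.model = model
        if model == "free_ratios":
            tree = tree.with_free_branch_groups()
        self.tree = tree
        self.n_groups = len(tree.group_names)
        if model in ("branch", "CmC") and self.n_groups < 2:
            raise ValueError(f"model {model} requires labeled branch groups")
        if model in ("BSM_A", "BSM_A_null") and self.n_groups != 2:
            raise ValueError(
                "branch-site model A requires exactly one foreground group"
            )
        self.names, self.lo, self.hi = self._parameter_table()

    def _parameter_table(self):
        lk = np.log(KAPPA_BOUNDS)
        lw = np.log(OMEGA_BOUNDS)
        names = ["log_kappa"]
        lo, hi = [lk[0]], [lk[1]]

        def add(name, lo_v, hi_v):
            names.append(name)
            lo.append(lo_v)
            hi.append(hi_v)

        m = self.model
        if m == "M0":
            add("log_omega", *lw)
        elif m in ("free_ratios", "branch"):
            for g in self.tree.group_names:
                add(f"log_omega:{g}", *lw)
        elif m in ("M2a_rel", "CmC", "BSM_A", "BSM_A_null"):
            add("logit_p0", -LOGIT_BOUND, LOGIT_BOUND)
            add("logit_p1", -LOGIT_BOUND, LOGIT_BOUND)
            add("log_omega0", lw[0], 0.0)  # purifying class: omega0 <= 1
            if m == "M2a_rel":
                add("log_omega2", *lw)
            elif m == "CmC":
                for g in self.tree.group_names:
                    add(f"log_omega2:{g}", *lw)
            elif m == "BSM_A":
                add("log_omega2", 0.0, lw[1])  # selected class: omega2 >= 1
        return names, np.array(lo), np.array(hi)

    @property
    def n_free(self) -> int:
        return len(self.names)

    # ------------------------------------------------------------------
    def layout(self, theta: np.ndarray):
        """(omega_values, omega_idx, weights) for a parameter vector."""
        tree = self.tree
        n_nodes = tree.n_nodes
        m = self.model
        kappa = float(np.exp(theta[0]))
        if m == "M0":
            values = np.array([np.exp(theta[1])])
            idx = np.zeros((n_nodes, 1), dtype=np.intp)
            weights = np.array([1.0])
        elif m in ("free_ratios", "branch"):
            values = np.exp(theta[1:])
            idx = tree.group[:, None].astype(np.intp)
            weights = np.array([1.0])
        else:
            p0 = _sigmoid(theta[1])
            p1 = (1 - p0) * _sigmoid(theta[2])
            p2 = 1 - p0 - p1
            omega0 = np.exp(theta[3])
            if m == "M2a_rel":
                omega2 = np.exp(theta[4])
                values = np.array([omega0, 1.0, omega2])
                idx = np.tile([0, 1, 2], (n_nodes, 1)).astype(np.intp)
                weights = np.array([p0, p1, p2])
            elif m == "CmC":
                omega2 = np.exp(theta[4:])
                values = np.concatenate([[omega0, 1.0], omega2])
                idx = np.tile([0, 1, 0], (n_nodes, 1)).astype(np.intp)
                idx[:, 2] = 2 + tree.group
                weights = np.array([p0, p1, p2])
            else:  # branch-site model A and its omega2=1 null
                omega2 = np.exp(theta[4]) if m == "BSM_A" else 1.0
                values = np.array([omega0, 1.0, omega2])
                fg = tree.group == 1
                # classes: 0, 1, 2a (0 on background), 2b (1 on background)
                idx = np.tile([0, 1, 0, 1], (n_nodes, 1)).astype(np.intp)
                idx[fg, 2] = 2
                idx[fg, 3] = 2
                denom = p0 + p1
                weights = np.array(
                    [p0, p1, p2 * p0 / denom, p2 * p1 / denom]
                )
            weights = np.clip(weights, 1e-12, None)
            weights = weights / weights.sum()
        return kappa, values, idx, weights

    def params_dict(self, theta: np.ndarray) -> dict:
        kappa, values, _, weights = self.layout(theta)
        m = self.model
        out: dict = {"kappa": kappa}
        if m == "M0":
            out["omega"] = float(values[0])
        elif m in ("free_ratios", "branch"):
            out["omega_by_group"] = {
                g: float(v) for g, v in zip(self.tree.group_names, values)
            }
        elif m == "M2a_rel":
            out.update(
                p0=float(weights[0]), p1=float(weights[1]), p2=float(weights[2]),
                omega0=float(values[0]), omega2=float(values[2]),
            )
        elif m == "CmC":
            out.update(
                p0=float(weights[0]), p1=float(weights[1]), p2=float(weights[2]),
                omega0=float(values[0]),
                omega2_by_group={
                    g: float(v)
                    for g, v in zip(self.tree.group_names, values[2:])
                },
            )
        else:
            out.update(
                p0=float(weights[0]), p1=float(weights[1]),
                p2a=float(weights[2]), p2b=float(weights[3]),
                omega0=float(values[0]), omega2=float(values[2]),
            )
        return out

    # ------------------------------------------------------------------
    def default_start(self) -> np.ndarray:
        theta = np.zeros(self.n_free)
        theta[0] = np.log(2.0)  # kappa
        for i, name in enumerate(self.names):
            if name.startswith("log_omega2"):
                theta[i] = np.log(1.5) if self.model == "BSM_A" else np.log(0.8)
            elif name.startswith("log_omega0"):
                theta[i] = np.log(0.1)
            elif name.startswith("log_omega"):
                theta[i] = np.log(0.3)
            elif name == "logit_p0":
                theta[i] = _logit(0.6)
            elif name == "logit_p1":
                theta[i] = _logit(0.5)
        return theta

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        span = self.hi - self.lo
        margin = 0.1 * span
        return rng.uniform(self.lo + margin, self.hi - margin)


def fit_model(
    aln: CodonAlignment,
    tree: LabeledTree,
    model: str,
    pi: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
    start: "CodonModelFit | np.ndarray | None" = None,
    ftol: float = 1e-10,
    max_iter: int = 500,
    engine: PruningEngine | None = None,
    use_default_start: bool = True,
) -> CodonModelFit:
    """Maximize the codon-model likelihood over kappa and the omega structure.

    Branch lengths are fixed to the input tree.  ``n_starts`` counts the
    deterministic default start plus seeded random restarts; an explicit
    ``start`` (for example the fitted null of a nested pair) is used as an
    additional warm start.  ``use_default_start=False`` drops the default
    start when a warm start is supplied — useful in replicate studies
    where the previous replicate's solution is a better starting point.
    """
    spec = _ModelSpec(model, tree)
    if engine is None:
        if pi is None:
            pi = f3x4_frequencies(aln.rows, aln.table_id)
        engine = PruningEngine(aln, spec.tree, pi)
    evals = 0

    def objective(theta):
        nonlocal evals
        evals += 1
        kappa, values, idx, weights = spec.layout(theta)
        lnl = engine.log_likelihood(kappa, values, idx, weights)
        return 1e12 if not np.isfinite(lnl) else -lnl

    rng = np.random.default_rng(seed)
    starts = [] if (start is not None and not use_default_start) else [
        spec.default_start()
    ]
    if start is not None:
        warm = start.theta if isinstance(start, CodonModelFit) else np.asarray(start)
        if len(warm) == spec.n_free:
            starts.append(warm.copy())
        elif model == "CmC" and len(warm) == spec.n_free - (spec.n_groups - 1):
            # M2a_rel fit warming a CmC fit: replicate omega2 per group
            starts.append(
                np.concatenate([warm[:4], np.repeat(warm[4], spec.n_groups)])
            )
        elif model == "BSM_A" and len(warm) == spec.n_free - 1:
            starts.append(np.concatenate([warm, [np.log(1.0) + 0.2]]))
    for _ in range(max(0, n_starts - 1)):
        starts.append(spec.random_start(rng))

    bounds = list(zip(spec.lo, spec.hi))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            np.clip(x0, spec.lo, spec.hi),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "maxiter": max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    return CodonModelFit(
        model=model,
        lnl=-float(best.fun),
        kappa=float(np.exp(theta[0])),
        params=spec.params_dict(theta),
        n_free_params=spec.n_free,
        converged=bool(best.success),
        n_evaluations=evals,
        n_starts=len(starts),
        theta=theta,
        group_names=list(spec.tree.group_names),
    )


def lrt(
    null_fit: CodonModelFit,
    alt_fit: CodonModelFit,
    df: int | None = None,
    tolerance: float = 1e-2,
) -> LRTResult:
    """Likelihood ratio test of two nested fits against chi2_df.

    The statistic is clipped at zero; a negative value beyond
    ``tolerance`` indicates an optimizer failure and raises.
    """
    if df is None:
        df = alt_fit.n_free_params - null_fit.n_free_params
    if df < 1:
        raise ValueError("models are not nested (df < 1)")
    raw = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if raw < -tolerance:
        raise RuntimeError(
            f"alternative lnL below null by {-raw/2:.4g}: optimizer failure"
        )
    statistic = max(0.0, raw)
    return LRTResult(
        null_model=null_fit.model,
        alt_model=alt_fit.model,
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
    )


NESTED_PAIRS = {
    ("M2a_rel", "CmC"),
    ("BSM_A_null", "BSM_A"),
    ("M0", "branch"),
    ("M0", "free_ratios"),
    ("branch", "free_ratios"),
}


def _project_alt_to_null(null_model: str, alt_fit: CodonModelFit) -> np.ndarray | None:
    """Map a fitted alternative onto the null's parameter space (warm start)."""
    theta = alt_fit.theta
    if (null_model, alt_fit.model) == ("M2a_rel", "CmC"):
        return np.concatenate([theta[:4], [np.log(np.exp(theta[4:]).mean())]])
    if (null_model, alt_fit.model) == ("BSM_A_null", "BSM_A"):
        return theta[:4].copy()
    if (null_model, alt_fit.model) in (("M0", "branch"), ("M0", "free_ratios")):
        return np.array([theta[0], np.log(np.exp(theta[1:]).mean())])
    return None


def nested_lrt(
    aln: CodonAlignment,
    tree: LabeledTree,
    null_model: str,
    alt_model: str,
    pi: np.ndarray | None = None,
    n_starts: int = 1,
    seed: int = 0,
    df: int | None = None,
    null_start: np.ndarray | None = None,
    alt_start: np.ndarray | None = None,
) -> tuple[CodonModelFit, CodonModelFit, LRTResult]:
    """Fit a nested model pair and test it, guarding against local optima.

    The alternative is warm-started from the null; the null is then
    re-fit warm-started from the alternative's projection and the better
    null kept, so the statistic can only shrink toward honesty.
    ``null_start`` supplies an extra warm start for the null fit (for
    example the previous replicate's solution in a simulation study).
    """
    if (null_model, alt_model) not in NESTED_PAIRS:
        raise ValueError(f"{null_model} is not nested in {alt_model}")
    if pi is None:
        pi = f3x4_frequencies(aln.rows, aln.table_id)
    # one engine serves every fit: same taxa, tree and frequencies, and the
    # transition-matrix cache carries over between the nested fits
    engine = None
    if "free_ratios" not in (null_model, alt_model):
        engine = PruningEngine(aln, tree, pi)
    null_fit = fit_model(
        aln, tree, null_model, pi=pi, n_starts=n_starts, seed=seed,
        engine=engine, start=null_start,
        use_default_start=null_start is None,
    )
    # the null-projected start makes lnL_alt >= lnL_null by construction,
    # so the alternative needs no separate default start
    alt_fit = fit_model(
        aln, tree, alt_model, pi=pi, n_starts=n_starts, seed=seed,
        start=null_fit, engine=engine, use_default_start=False,
    )
    if alt_start is not None and len(alt_start) == len(alt_fit.theta):
        alt_retry = fit_model(
            aln, tree, alt_model, pi=pi, n_starts=1, seed=seed,
            start=alt_start, engine=engine, use_default_start=False,
        )
        if alt_retry.lnl > alt_fit.lnl:
            alt_fit = alt_retry
    warm = _project_alt_to_null(null_model, alt_fit)
    if warm is not None:
        refit = fit_model(
            aln, tree, null_model, pi=pi, n_starts=1, seed=seed, start=warm,
            engine=engine, use_default_start=False,
        )
        if refit.lnl > null_fit.lnl:
            null_fit = refit
    return null_fit, alt_fit, lrt(null_fit, alt_fit, df=df)


def mass_omega_correlation(
    masses_kg, omegas, method: str = "pearson"
) -> tuple[float, float]:
    """Association between species body mass and terminal-branch omega.

    Returns (r, two-sided p).  Raises on fewer than 3 pairs or zero
    variance in either vector.
    """
    x = np.asarray(masses_kg, dtype=float)
    y = np.asarray(omegas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if len(x) < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
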