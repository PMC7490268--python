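"""Branch and branch-site codon models: M0, two-ratio, Model A, LRTs.

The model hierarchy assigns dN/dS (omega) values to combinations of site
classes and branch categories (background vs. tagged foreground):

====================  ==========================================================
M0                    one omega for every site and branch
two-ratio             omega0 on background branches, omega1 on the foreground
Model A null          site classes 0/1/2a/2b with the foreground class omega
                      fixed at 1
Model A               as the null but the foreground class omega2 >= 1 is free
====================  ==========================================================

The ``np`` bookkeeping counts only the parameters of the omega
distribution (M0: 1, two-ratio: 2, Model A null: 3, Model A: 4); kappa and
branch lengths are nuisance parameters estimated alongside.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from ..alignment import CodonAlignment
from ..trees import LabeledTree
from .gy94 import SpectralPropagator, build_rate_matrix, equal_frequencies, f3x4_frequencies
from .likelihood import PruningEngine

#: omega values at or beyond this cap are reported as exactly 999.0 with a
#: dS-zero flag, following the reporting convention of codeml-family tools
#: when the synonymous-rate denominator vanishes.
OMEGA_CAP = 999.0

MODELS = ("M0", "two_ratio", "modelA_null", "modelA")
_NP = {"M0": 1, "two_ratio": 2, "modelA_null": 3, "modelA": 4}
_BRANCH_MODELS = {"two_ratio", "modelA_null", "modelA"}

_LOG_OMEGA_LO, _LOG_OMEGA_HI = np.log(1e-4), np.log(OMEGA_CAP)
_LOG_KAPPA_LO, _LOG_KAPPA_HI = np.log(0.05), np.log(50.0)
_LOG_BL_LO, _LOG_BL_HI = np.log(1e-5), np.log(20.0)
_MIX_LO, _MIX_HI = -12.0, 12.0


def _split_class2(p0: float, p1: float):
    """Proportions of classes 2a/2b: the remainder split proportionally."""
    p2 = max(0.0, 1.0 - p0 - p1)
    s = p0 + p1
    if s <= 0:
        return 0.5 * p2, 0.5 * p2
    return p2 * p0 / s, p2 * p1 / s


def model_site_classes(model: str, params: dict):
    """Site-class table: list of (weight, omega_background, omega_foreground)."""
    if model == "M0":
        return [(1.0, params["omega"], params["omega"])]
    if model == "two_ratio":
        return [(1.0, params["omega0"], params["omega1"])]
    if model in ("modelA", "modelA_null"):
        p0, p1 = params["p0"], params["p1"]
        w0 = params["omega0"]
        w2 = 1.0 if model == "modelA_null" else params["omega2"]
        p2a, p2b = _split_class2(p0, p1)
        return [(p0, w0, w0), (p1, 1.0, 1.0), (p2a, w0, w2), (p2b, 1.0, w2)]
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


MODEL_A_CLASS_NAMES = ("0", "1", "2a", "2b")


@dataclass
class CodonModelFit:
    """A fitted codon model, mirroring one row of a selection-analysis table."""

    model: str
    np_omega: int
    lnL: float
    kappa: float
    params: dict
    branch_lengths: dict
    pi: np.ndarray = field(repr=False)
    converged: bool = True
    n_starts: int = 1
    ds_zero: bool = False
    alignment: CodonAlignment | None = field(default=None, repr=False)
    tree: LabeledTree | None = field(default=None, repr=False)

    def summary(self) -> dict:
        out = {
            "model": self.model,
            "np": self.np_omega,
            "lnL": round(self.lnL, 3),
            "kappa": round(self.kappa, 4),
            "converged": self.converged,
        }
        out.update({k: round(v, 4) for k, v in self.params.items()})
        if self.ds_zero:
            out["ds_zero"] = True
        return out


def _class_pattern_logliks(engine: PruningEngine, pi, kappa, classes, lengths):
    """Per-class pattern log-likelihoods sharing propagators across classes."""
    code = engine.alignment.code
    props: dict = {}
    by_branch_len = dict(zip((id(b) for b in engine.branches), lengths))

    out = []
    for _, om_bg, om_fg in classes:
        def P_of(node, _bg=om_bg, _fg=om_fg):
            om = _fg if node.foreground else _bg
            prop = props.get(om)
            if prop is None:
                prop = SpectralPropagator(build_rate_matrix(code, kappa, om, pi), pi)
                props[om] = prop
            return prop.prob(by_branch_len[id(node)])

        out.append(engine.pattern_logliks(P_of, pi))
    return np.array(out)  # (n_classes, n_patterns)


def _mixture_loglik(engine, pi, kappa, classes, lengths) -> float:
    weights = np.array([c[0] for c in classes])
    logs = _class_pattern_logliks(engine, pi, kappa, classes, lengths)
    m = logs.max(axis=0)
    mixed = np.log(np.clip(weights @ np.exp(logs - m), 1e-300, None)) + m
    return engine.total_loglik(mixed)


def log_likelihood(alignment: CodonAlignment, tree: LabeledTree, model: str,
                   params: dict, kappa: float, pi: np.ndarray | None = None) -> float:
    """Log-likelihood of the data under ``model`` at fixed parameter values."""
    engine = PruningEngine(alignment, tree)
    if pi is None:
        pi = equal_frequencies(alignment.code)
    classes = model_site_classes(model, params)
    if model in _BRANCH_MODELS and not tree.has_foreground():
        warnings.warn(f"{model} requested on a tree with no foreground branches")
    return _mixture_loglik(engine, pi, kappa, classes, engine.branch_lengths())


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _pack_spec(model: str):
    """Names of the free omega-distribution parameters, in pack order."""
    if model == "M0":
        return ["omega"]
    if model == "two_ratio":
        return ["omega0", "omega1"]
    if model == "modelA_null":
        return ["p0", "p1", "omega0"]
    return ["p0", "p1", "omega0", "omega2"]


def _unpack(model: str, x: np.ndarray, n_branch: int, fix_bl, kappa_fixed):
    """x -> (kappa, params dict, branch lengths)."""
    i = 0
    if kappa_fixed is None:
        kappa = float(np.exp(x[i])); i += 1
    else:
        kappa = kappa_fixed
    params: dict = {}
    if model in ("modelA", "modelA_null"):
        a, b = x[i], x[i + 1]; i += 2
        z = 1.0 + np.exp(a) + np.exp(b)
        params["p0"], params["p1"] = float(np.exp(a) / z), float(np.exp(b) / z)
        params["omega0"] = float(np.exp(x[i])); i += 1
        if model == "modelA":
            params["omega2"] = 1.0 + float(np.exp(x[i])); i += 1
    elif model == "M0":
        params["omega"] = float(np.exp(x[i])); i += 1
    else:
        params["omega0"] = float(np.exp(x[i])); i += 1
        params["omega1"] = float(np.exp(x[i])); i += 1
    if fix_bl is not None:
        lengths = fix_bl
    else:
        lengths = np.exp(x[i : i + n_branch])
    return kappa, params, lengths


def _initial_points(model, engine, kappa0, fix_bl, kappa_fixed, n_starts, rng):
    bl0 = np.clip(engine.branch_lengths(), 2e-5, 19.0)
    base = []
    if kappa_fixed is None:
        base.append(np.log(kappa0))
    if model in ("modelA", "modelA_null"):
        base += [np.log(0.6 / 0.25), np.log(0.15 / 0.25)]  # p ~ (0.6, 0.15)
        base.append(np.log(0.2))
        if model == "modelA":
            base.append(np.log(1.5))  # omega2 = 2.5
    elif model == "M0":
        base.append(np.log(0.4))
    else:
        base += [np.log(0.4), np.log(0.4)]
    base = np.array(base)
    points = []
    for k in range(n_starts):
        x = base if k == 0 else base + rng.normal(0, 0.7, size=base.size)
        if fix_bl is None:
            x = np.concatenate([x, np.log(bl0)])
        points.append(x)
    return points


def _bounds(model, n_branch, fix_bl, kappa_fixed):
    bounds = []
    if kappa_fixed is None:
        bounds.append((_LOG_KAPPA_LO, _LOG_KAPPA_HI))
    if model in ("modelA", "modelA_null"):
        bounds += [(_MIX_LO, _MIX_HI)] * 2
        bounds.append((_LOG_OMEGA_LO, np.log(2.0)))  # class-0 omega < 1 territory
        if model == "modelA":
            bounds.append((np.log(1e-6), np.log(OMEGA_CAP - 1.0)))
    elif model == "M0":
        bounds.append((_LOG_OMEGA_LO, _LOG_OMEGA_HI))
    else:
        bounds += [(_LOG_OMEGA_LO, _LOG_OMEGA_HI)] * 2
    if fix_bl is None:
        bounds += [(_LOG_BL_LO, _LOG_BL_HI)] * n_branch
    return bounds


def fit(
    alignment: CodonAlignment,
    tree: LabeledTree,
    model: str = "M0",
    *,
    freq_mode: str = "F3x4",
    kappa_init: float = 2.0,
    fix_kappa: float | None = None,
    fix_branch_lengths: bool = False,
    n_starts: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> CodonModelFit:
    """Maximum-likelihood fit of a codon model.

    Parameters
    ----------
    model : {"M0", "two_ratio", "modelA_null", "modelA"}
    freq_mode : {"F3x4", "equal"}
        Codon equilibrium frequencies: estimated from position-specific
        nucleotide composition (default) or uniform.
    fix_branch_lengths : bool
        Keep the input tree's branch lengths instead of re-estimating them
        (useful for large simulation batteries).
    n_starts : int
        Multi-start count; starts beyond the first are jittered.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if model in _BRANCH_MODELS and not tree.has_foreground():
        raise ValueError(f"{model} requires a tree with #1 foreground branch tags")
    engine = PruningEngine(alignment, tree)
    if freq_mode == "F3x4":
        pi = f3x4_frequencies(alignment)
    elif freq_mode == "equal":
        pi = equal_frequencies(alignment.code)
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")

    fix_bl = engine.branch_lengths() if fix_branch_lengths else None
    n_branch = len(engine.branches)
    rng = np.random.default_rng(seed)

    def objective(x):
        kappa, params, lengths = _unpack(model, x, n_branch, fix_bl, fix_kappa)
        classes = model_site_classes(model, params)
        try:
            return -_mixture_loglik(engine, pi, kappa, classes, lengths)
        except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
            return 1e12

    best = None
    converged = False
    bounds = _bounds(model, n_branch, fix_bl, fix_kappa)
    for x0 in _initial_points(model, engine, kappa_init, fix_bl, fix_kappa, n_starts, rng):
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged
    if not converged:
        warnings.warn(f"{model} fit did not report convergence after {n_starts} starts")

    kappa, params, lengths = _unpack(model, best.x, n_branch, fix_bl, fix_kappa)
    ds_zero = False
    for key in ("omega", "omega1", "omega2"):
        if key in params and params[key] >= OMEGA_CAP - 1.0:
            params[key] = OMEGA_CAP
            ds_zero = True
    bl = {
        (b.name or f"node{i}"): float(t)
        for i, (b, t) in enumerate(zip(engine.branches, lengths))
    }
    return CodonModelFit(
        model=model,
        np_omega=_NP[model],
        lnL=-float(best.fun),
        kappa=kappa,
        params=params,
        branch_lengths=bl,
        pi=pi,
        converged=converged,
        n_starts=n_starts,
        ds_zero=ds_zero,
        alignment=alignment,
        tree=tree,
    )


def lrt(fit_null: CodonModelFit, fit_alt: CodonModelFit):
    """Likelihood-ratio test of nested codon models.

    Returns ``(statistic, df, p)`` with the statistic 2(lnL_alt - lnL_null)
    clipped at zero and df the difference in omega-distribution parameters.
    """
    nested = {("M0", "two_ratio"), ("modelA_null", "modelA")}
    if (fit_null.model, fit_alt.model) not in nested:
        raise ValueError(
            f"{fit_alt.model} is not the nested alternative of {fit_null.model}"
        )
    if fit_alt.np_omega <= fit_null.np_omega:
        raise ValueError("alternative must have more free parameters than the null")
    stat = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    df = fit_alt.np_omega - fit_null.np_omega
    return stat, df, float(chi2.sf(stat, df))


def site_posteriors(model_fit: CodonModelFit) -> np.ndarray:
    """Naive empirical-Bayes posterior over site classes at the MLEs.

    Only defined for the branch-site models; returns an array of shape
    (n_sites, 4) over classes 0/1/2a/2b, each row summing to one.
    """
    if model_fit.model not in ("modelA", "modelA_null"):
        raise ValueError(f"site posteriors are undefined for {model_fit.model}")
    if model_fit.alignment is None or model_fit.tree is None:
        raise ValueError("fit does not retain its data; refit with the library API")
    engine = PruningEngine(model_fit.alignment, model_fit.tree)
    classes = model_site_classes(model_fit.model, model_fit.params)
    lengths = np.array(
        [model_fit.branch_lengths[b.name or f"node{i}"]
         for i, b in enumerate(engine.branches)]
    )
    logs = _class_pattern_logliks(engine, model_fit.pi, model_fit.kappa, classes, lengths)
    weights = np.array([c[0] for c in classes])
    logw = np.log(np.clip(weights, 1e-300, None))
    joint = logw[:, None] + logs
    joint -= joint.max(axis=0, keepdims=True)
    post = np.exp(joint)
    post /= post.sum(axis=0, keepdims=True)
    return post.T[engine.pattern_of_site]


def positive_site_report(model_fit: CodonModelFit, reference_taxon: str,
                         threshold: float = 0.5) -> list:
    """Sites with high posterior in the positively selected classes (2a+2b).

    Each entry is ``(token, posterior)`` with the token formatted as
    position + reference amino acid, e.g. ``"57N"``.
    """
    post = site_posteriors(model_fit)
    aln = model_fit.alignment
    ref = aln.row(reference_taxon)
    code = aln.code
    out = []
    for pos, p2 in enumerate(post[:, 2] + post[:, 3], start=1):
        if p2 >= threshold:
            aa = code.amino_acids[ref[pos - 1]]
            out.append((f"{pos}{aa}", float(p2)))
    return out


@dataclass(frozen=True)
class SelectionCall:
    """Selection-pressure label for an omega estimate."""

    omega: float
    label: str  # positive | purifying | neutral_boundary
    ds_zero: bool = False


def classify_selection(omega: float, ds_zero: bool = False) -> SelectionCall:
    """Label an omega estimate: >1 positive, in (0,1) purifying, =1 boundary."""
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    if omega > 1:
        label = "positive"
    elif omega == 1:
        label = "neutral_boundary"
    else:
        label = "purifying"
    return SelectionCall(omega=omega, label=label, ds_zero=ds_zero)
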