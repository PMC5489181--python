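"""Robust-design open-population capture-recapture model.

The model is a three-state hidden Markov chain over primary occasions — states
*on-grid* (available for detection), *off-grid* (temporarily emigrated) and
*dead* — with a closed-capture binomial emission within each primary.  Annual
apparent survival phi governs leaving the live states; temporary emigration is
parameterised by gamma'' (probability an on-grid animal is off-grid next year)
and gamma' (probability an off-grid animal stays off-grid), with the *random*
constraint gamma' = gamma'', the *Markovian* model leaving both free, and the
*no-emigration* model fixing gamma'' = 0, gamma' = 1.  Detection uses a single
per-occasion probability p (capture = recapture), structured over sex, camera
era (film/digital) and optionally year-within-era.

The likelihood is conditional on first capture (Huggins-style): the first
detected primary's emission is divided by p* = 1 - (1-p)^K, and subsequent
primaries are handled by a forward algorithm; abundance is a derived quantity
n_t / p*_t rather than a parameter.  Multi-year gaps between primaries use the
one-year transition matrix raised to the gap length, i.e. annual rates applied
per calendar year.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.linalg import matrix_power
from scipy.optimize import minimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess

from .errors import FitError
from .survey import CaptureHistory, SurveyDesign

# hidden states
ONGRID, OFFGRID, DEAD = 0, 1, 2

_SEX_CODE = {"male": 0, "female": 1}

PHI_STRUCTURES = (".", "sex", "time", "sex*time", "sex(time/.)", "sex(./time)")
P_STRUCTURES = (
    ".", "sex", "time", "sex*time", "era", "sex*era",
    "era(./time)", "sex*era(./time)",
)
GAMMA_MODES = ("random", "markovian", "none")
GAMMA_TIMES = (".", "time")


# ---------------------------------------------------------------------------
# model structure and parameter indexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelStructure:
    """A constraint specification for (phi, gamma, p) with p = c throughout."""

    phi: str = "."
    gamma_mode: str = "random"
    gamma_time: str = "."
    p: str = "sex*era(./time)"

    def __post_init__(self) -> None:
        if self.phi not in PHI_STRUCTURES:
            raise ValueError(f"unknown phi structure {self.phi!r}")
        if self.p not in P_STRUCTURES:
            raise ValueError(f"unknown p structure {self.p!r}")
        if self.gamma_mode not in GAMMA_MODES:
            raise ValueError(f"unknown gamma mode {self.gamma_mode!r}")
        if self.gamma_time not in GAMMA_TIMES:
            raise ValueError(f"unknown gamma time structure {self.gamma_time!r}")

    @property
    def uses_sex(self) -> bool:
        return "sex" in self.phi or "sex" in self.p

    @property
    def name(self) -> str:
        g = "none" if self.gamma_mode == "none" else f"{self.gamma_mode},{self.gamma_time}"
        return f"phi({self.phi}) gamma({g}) p({self.p})"

    def __str__(self) -> str:  # pragma: no cover
        return self.name


_DSL = re.compile(
    r"phi\((?P<phi>[^)]*(?:\([^)]*\))?[^)]*)\)\s+"
    r"gamma\((?P<gamma>[^)]*)\)\s+"
    r"p\((?P<p>.*)\)$"
)


def parse_structure(text: str) -> ModelStructure:
    """Parse a structure DSL string such as
    ``"phi(.) gamma(random,.) p(sex*era(./time))"``."""
    m = _DSL.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse model structure: {text!r}")
    gamma = m.group("gamma").strip()
    if gamma == "none":
        mode, gtime = "none", "."
    else:
        parts = [s.strip() for s in gamma.split(",")]
        mode = parts[0]
        gtime = parts[1] if len(parts) > 1 else "."
    return ModelStructure(
        phi=m.group("phi").strip(),
        gamma_mode=mode,
        gamma_time=gtime,
        p=m.group("p").strip(),
    )


def _index_from_keys(keys, offset):
    """Map a list of hashable keys to consecutive integer indices (first
    appearance order), starting at ``offset``."""
    seen: dict = {}
    idx = []
    for k in keys:
        if k not in seen:
            seen[k] = offset + len(seen)
        idx.append(seen[k])
    return np.array(idx, dtype=int), offset + len(seen)


@dataclass
class ParameterMap:
    """Maps each real parameter slot of a structure x design to one logit-scale
    coefficient (the structures here are partitions, so every slot has exactly
    one coefficient; the no-emigration gammas are fixed and carry none)."""

    structure: ModelStructure
    design: SurveyDesign
    idx_phi: np.ndarray  # (T-1, 2) -> beta index
    idx_gpp: np.ndarray  # (T-1,) or empty; -1 where fixed
    idx_gp: np.ndarray   # (T-1,)
    idx_p: np.ndarray    # (T, 2)
    n_params: int

    @classmethod
    def build(cls, structure: ModelStructure, design: SurveyDesign) -> "ParameterMap":
        T = design.n_primaries
        eras = design.eras
        off = 0

        def phi_key(j, s):
            return {
                ".": 0,
                "sex": s,
                "time": j,
                "sex*time": (s, j),
                "sex(time/.)": (0, j) if s == 0 else "f",
                "sex(./time)": "m" if s == 0 else (1, j),
            }[structure.phi]

        keys = [phi_key(j, s) for j in range(T - 1) for s in (0, 1)]
        flat, off = _index_from_keys(keys, off)
        idx_phi = flat.reshape(T - 1, 2) if T > 1 else np.zeros((0, 2), dtype=int)

        if structure.gamma_mode == "none" or T == 1:
            idx_gpp = np.full(max(T - 1, 0), -1, dtype=int)
            idx_gp = np.full(max(T - 1, 0), -1, dtype=int)
        else:
            gkeys = [0 if structure.gamma_time == "." else j for j in range(T - 1)]
            idx_gpp, off = _index_from_keys(gkeys, off)
            if structure.gamma_mode == "random":
                idx_gp = idx_gpp.copy()
            else:
                idx_gp, off = _index_from_keys(gkeys, off)

        def p_key(t, s):
            e = eras[t]
            era_time = ("film",) if e == "film" else ("dig", t)
            return {
                ".": 0,
                "sex": s,
                "time": t,
                "sex*time": (s, t),
                "era": e,
                "sex*era": (s, e),
                "era(./time)": era_time,
                "sex*era(./time)": (s,) + era_time,
            }[structure.p]

        pkeys = [p_key(t, s) for t in range(T) for s in (0, 1)]
        flat, off = _index_from_keys(pkeys, off)
        idx_p = flat.reshape(T, 2)

        return cls(structure, design, idx_phi, idx_gpp, idx_gp, idx_p, off)

    def realize(self, beta: np.ndarray):
        """Inverse-logit the coefficients into real-scale parameter arrays
        phi (T-1, 2), gamma'' (T-1,), gamma' (T-1,), p (T, 2)."""
        beta = np.asarray(beta, dtype=float)
        theta = expit(beta)
        phi = theta[self.idx_phi] if self.idx_phi.size else np.zeros((0, 2))
        if self.structure.gamma_mode == "none":
            gpp = np.zeros(len(self.idx_gpp))
            gp = np.ones(len(self.idx_gp))
        else:
            gpp = theta[self.idx_gpp] if self.idx_gpp.size else np.zeros(0)
            gp = theta[self.idx_gp] if self.idx_gp.size else np.zeros(0)
        p = theta[self.idx_p]
        return phi, gpp, gp, p


# ---------------------------------------------------------------------------
# likelihood building blocks
# ---------------------------------------------------------------------------

def transition_matrix(
    phi: float, gamma_pp: float, gamma_p: float, dt: int = 1
) -> np.ndarray:
    """Annual transition matrix over (on-grid, off-grid, dead), raised to the
    ``dt``-th power for multi-year gaps between primaries."""
    if dt < 1:
        raise ValueError("dt must be >= 1")
    for name, v in (("phi", phi), ("gamma_pp", gamma_pp), ("gamma_p", gamma_p)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    M = np.array(
        [
            [phi * (1 - gamma_pp), phi * gamma_pp, 1 - phi],
            [phi * (1 - gamma_p), phi * gamma_p, 1 - phi],
            [0.0, 0.0, 1.0],
        ]
    )
    return M if dt == 1 else matrix_power(M, dt)


def emission_prob(secondary_history: Sequence[int], state: int, p: float) -> float:
    """Probability of a within-primary secondary history given the state.

    On-grid: independent Bernoulli(p) per occasion; off-grid and dead can only
    produce the all-zero history.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    y = np.asarray(secondary_history)
    if state == ONGRID:
        return float(np.prod(np.where(y == 1, p, 1.0 - p)))
    return 1.0 if not y.any() else 0.0


def history_loglik(
    detections: np.ndarray,
    first: int,
    phi: np.ndarray,
    gamma_pp: np.ndarray,
    gamma_p: np.ndarray,
    p: np.ndarray,
    design: SurveyDesign,
) -> float:
    """Log-probability of one individual's history, conditional on being
    on-grid and detected at least once in its first detected primary.

    Reference (readable) implementation; the fitting path uses the vectorised
    equivalent in :func:`neg_loglik`.

    Parameters are real-scale per-slot arrays for this individual: ``phi``,
    ``gamma_pp``, ``gamma_p`` over the T-1 intervals and ``p`` over the T
    primaries.
    """
    T = design.n_primaries
    K = design.K
    intervals = design.intervals
    yf = detections[first, : K[first]]
    p_star = 1.0 - (1.0 - p[first]) ** K[first]
    if p_star <= 0.0:
        raise FloatingPointError("p* is zero at a primary with a detection")
    ll = np.log(emission_prob(yf, ONGRID, p[first])) - np.log(p_star)
    alpha = np.array([1.0, 0.0, 0.0])
    for t in range(first, T - 1):
        M = transition_matrix(phi[t], gamma_pp[t], gamma_p[t], intervals[t])
        alpha = alpha @ M
        y = detections[t + 1, : K[t + 1]]
        e = np.array(
            [
                emission_prob(y, ONGRID, p[t + 1]),
                emission_prob(y, OFFGRID, p[t + 1]),
                emission_prob(y, DEAD, p[t + 1]),
            ]
        )
        alpha = alpha * e
    return float(ll + np.log(alpha.sum() if first < T - 1 else 1.0))


@dataclass
class PackedData:
    """Capture histories reduced to sufficient statistics for fitting.

    Because p is constant within a primary, the within-primary emission
    depends only on the detection *count*; identical (sex, count-vector) rows
    are collapsed with weights.
    """

    counts: np.ndarray   # (n_unique, T)
    first: np.ndarray    # (n_unique,)
    sex: np.ndarray      # (n_unique,) 0 male / 1 female
    weights: np.ndarray  # (n_unique,)
    n_individuals: int
    fingerprint: tuple

    @classmethod
    def from_history(cls, data: CaptureHistory, structure: ModelStructure) -> "PackedData":
        sex_known = np.array([s != "unknown" for s in data.sexes])
        if structure.uses_sex and not sex_known.all():
            data = data.subset(sex_known)
        counts = data.counts
        sex = np.array([_SEX_CODE.get(s, 0) for s in data.sexes])
        key: dict = {}
        for i in range(counts.shape[0]):
            k = (int(sex[i]), tuple(int(c) for c in counts[i]))
            key[k] = key.get(k, 0) + 1
        uniq = sorted(key)
        c = np.array([k[1] for k in uniq], dtype=int).reshape(len(uniq), -1)
        s = np.array([k[0] for k in uniq], dtype=int)
        w = np.array([key[k] for k in uniq], dtype=float)
        f = np.argmax(c > 0, axis=1)
        fp = (counts.shape[0], int(counts.sum()), tuple(np.sort(sex)))
        return cls(c, f, s, w, counts.shape[0], fp)

    @property
    def effective_sample_size(self) -> float:
        """Sum over individuals of primaries from first capture through the
        last primary (the AICc sample-size convention used here)."""
        T = self.counts.shape[1]
        return float(np.sum(self.weights * (T - self.first)))


def neg_loglik(
    beta: np.ndarray,
    pm: ParameterMap,
    packed: PackedData,
) -> float:
    """Negative log-likelihood over all individuals (vectorised forward pass)."""
    phi, gpp, gp, p = pm.realize(beta)
    design = pm.design
    d = packed.counts
    n, T = d.shape
    if n == 0:
        return 0.0
    K = design.K
    sex = packed.sex
    f = packed.first
    w = packed.weights
    intervals = design.intervals

    p = np.clip(p, 1e-12, 1 - 1e-12)
    logp = np.log(p)
    log1mp = np.log1p(-p)
    # (n, T) log-emission in the on-grid state
    logeA = d * logp[:, sex].T + (K[None, :] - d) * log1mp[:, sex].T
    pstar = 1.0 - (1.0 - p) ** K[:, None]  # (T, 2)

    ar = np.arange(n)
    ll = logeA[ar, f] - np.log(pstar[f, sex])

    # precompute per-interval, per-sex transition matrices
    Ms = np.empty((max(T - 1, 0), 2, 3, 3))
    for t in range(T - 1):
        for s in (0, 1):
            Ms[t, s] = transition_matrix(
                float(phi[t, s]), float(gpp[t]), float(gp[t]), intervals[t]
            )

    alpha = np.zeros((n, 3))
    alpha[f == 0, 0] = 1.0
    for t in range(T - 1):
        started = f <= t
        # transition to primary t+1
        for s in (0, 1):
            rows = started & (sex == s)
            if rows.any():
                alpha[rows] = alpha[rows] @ Ms[t, s]
        # emission at t+1 for already-started individuals
        eA = np.exp(logeA[:, t + 1])
        ez = (d[:, t + 1] == 0).astype(float)
        em = np.column_stack([eA, ez, ez])
        alpha = np.where(started[:, None], alpha * em, alpha)
        tot = alpha.sum(axis=1)
        tot_safe = np.maximum(tot, 1e-300)
        ll = np.where(started, ll + np.log(tot_safe), ll)
        alpha = np.where(started[:, None], alpha / tot_safe[:, None], alpha)
        # individuals first detected at t+1 enter conditioned on-grid
        new = f == t + 1
        alpha[new] = 0.0
        alpha[new, 0] = 1.0

    val = -float(np.sum(w * ll))
    if not np.isfinite(val):
        return 1e12
    return val


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    structure: ModelStructure
    design: SurveyDesign
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_params: int
    n_eff: float
    aicc: float
    real: pd.DataFrame          # (param, sex, year, estimate, se, beta_index)
    converged: bool
    boundary: bool
    n_individuals: int
    data_fingerprint: tuple
    diagnostics: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.structure.name


def _real_table(pm: ParameterMap, beta: np.ndarray, vcov: np.ndarray) -> pd.DataFrame:
    """Expanded real-scale estimate grid: one row per (param, sex, year)."""
    design = pm.design
    years = design.years
    theta = expit(beta)
    se_beta = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf)) if len(beta) else np.zeros(0)
    rows = []

    def add(param, sex, year, bidx, fixed=None):
        if fixed is not None:
            rows.append((param, sex, year, fixed, 0.0, -1))
        else:
            est = theta[bidx]
            se = est * (1 - est) * se_beta[bidx]
            rows.append((param, sex, year, est, se, bidx))

    T = design.n_primaries
    for j in range(T - 1):
        for s, sname in enumerate(("male", "female")):
            add("phi", sname, years[j], int(pm.idx_phi[j, s]))
    for j in range(T - 1):
        if pm.structure.gamma_mode == "none":
            add("gamma_pp", "both", years[j], -1, fixed=0.0)
            add("gamma_p", "both", years[j], -1, fixed=1.0)
        else:
            add("gamma_pp", "both", years[j], int(pm.idx_gpp[j]))
            add("gamma_p", "both", years[j], int(pm.idx_gp[j]))
    for t in range(T):
        for s, sname in enumerate(("male", "female")):
            add("p", sname, years[t], int(pm.idx_p[t, s]))
    return pd.DataFrame(
        rows, columns=["param", "sex", "year", "estimate", "se", "beta_index"]
    )


def aicc(loglik: float, k: int, n_eff: float) -> float:
    """Small-sample Akaike information criterion."""
    if n_eff - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n_eff - k - 1)


def fit_model(
    structure: ModelStructure,
    data: CaptureHistory,
    design: SurveyDesign,
    n_starts: int = 10,
    seed: int | None = None,
    ess: str = "primaries",
    compute_vcov: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of one model structure.

    Quasi-Newton (L-BFGS-B) optimisation from ``n_starts`` initial coefficient
    vectors: the first at zero (all probabilities 0.5), the rest dispersed
    logit-uniform on (0.05, 0.95).  The best optimum is kept; the covariance is
    the inverse of the numerically differentiated observed information.

    ``ess`` selects the AICc sample size: ``"primaries"`` (sum over individuals
    of primaries from first capture to the end) or ``"individuals"``.
    """
    pm = ParameterMap.build(structure, design)
    packed = PackedData.from_history(data, structure)
    if packed.n_individuals == 0:
        raise FitError("no individuals to fit")
    rng = np.random.default_rng(seed)

    starts = [np.zeros(pm.n_params)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(logit(rng.uniform(0.05, 0.95, size=pm.n_params)))

    best = None
    n_ok = 0
    for x0 in starts:
        res = minimize(
            neg_loglik,
            x0,
            args=(pm, packed),
            method="L-BFGS-B",
            bounds=[(-15.0, 15.0)] * pm.n_params,
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError("all optimisation starts failed")

    beta = np.asarray(best.x, dtype=float)
    boundary = bool(np.any(np.abs(beta) > 10.0))
    if compute_vcov and pm.n_params:
        try:
            H = approx_hess(beta, neg_loglik, args=(pm, packed))
            vcov = np.linalg.pinv((H + H.T) / 2.0)
            vcov = np.where(np.diag(vcov)[:, None] >= 0, vcov, np.nan)
        except Exception:  # numerical failure on a ridge
            vcov = np.full((pm.n_params, pm.n_params), np.nan)
    else:
        vcov = np.zeros((pm.n_params, pm.n_params))

    loglik = -float(best.fun)
    n_eff = (
        packed.effective_sample_size
        if ess == "primaries"
        else float(packed.n_individuals)
    )
    real = _real_table(pm, beta, vcov)
    return FitResult(
        structure=structure,
        design=design,
        beta=beta,
        vcov=vcov,
        loglik=loglik,
        n_params=pm.n_params,
        n_eff=n_eff,
        aicc=aicc(loglik, pm.n_params, n_eff),
        real=real,
        converged=bool(best.success),
        boundary=boundary,
        n_individuals=packed.n_individuals,
        data_fingerprint=packed.fingerprint,
        diagnostics={"n_starts_ok": n_ok, "grad_norm": float(np.max(np.abs(best.jac)))},
    )


# ---------------------------------------------------------------------------
# derived abundance, model selection and averaging
# ---------------------------------------------------------------------------

def derived_abundance(
    fit: FitResult, data: CaptureHistory, design: SurveyDesign
) -> pd.DataFrame:
    """Per-sex, per-primary derived abundance N = n / p*.

    p*_t = 1 - (1 - p_t)^K_t; the standard error combines the binomial
    component n (1 - p*) / p*^2 with the detection-parameter uncertainty by
    the delta method.  Years with no detected individuals of a sex are flagged
    not estimable (NE).
    """
    K = design.K
    years = design.years
    seen = data.counts > 0
    sex_arr = np.array(data.sexes)
    rows = []
    preal = fit.real[fit.real["param"] == "p"]
    for sname in ("male", "female"):
        members = sex_arr == sname
        for t, year in enumerate(years):
            n_t = int(seen[members, t].sum())
            prow = preal[(preal["sex"] == sname) & (preal["year"] == year)].iloc[0]
            p_hat = float(prow["estimate"])
            if p_hat <= 0:
                raise FloatingPointError("p-hat is zero; abundance undefined")
            pstar = 1.0 - (1.0 - p_hat) ** K[t]
            if n_t == 0:
                rows.append((sname, year, 0, pstar, np.nan, np.nan, False))
                continue
            N = n_t / pstar
            var_binom = n_t * (1.0 - pstar) / pstar**2
            bidx = int(prow["beta_index"])
            if bidx >= 0 and np.isfinite(fit.vcov[bidx, bidx]):
                dN_dp = -n_t * K[t] * (1.0 - p_hat) ** (K[t] - 1) / pstar**2
                dp_db = p_hat * (1.0 - p_hat)
                var_par = (dN_dp * dp_db) ** 2 * fit.vcov[bidx, bidx]
            else:
                var_par = 0.0
            rows.append((sname, year, n_t, pstar, N, np.sqrt(var_binom + var_par), True))
    return pd.DataFrame(
        rows, columns=["sex", "year", "n", "p_star", "N_hat", "se", "estimable"]
    )


def akaike_weights(aicc_values: Sequence[float]) -> pd.DataFrame:
    """Delta-AICc, model likelihoods exp(-delta/2) and normalised weights."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    lik = np.exp(-delta / 2.0)
    w = lik / lik.sum()
    return pd.DataFrame(
        {"aicc": a, "delta_aicc": delta, "model_likelihood": lik, "weight": w}
    )


def aicc_weights(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Model-comparison table over fits of the *same* data."""
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits were made on different datasets")
    tab = akaike_weights([f.aicc for f in fits])
    tab.insert(0, "model", [f.name for f in fits])
    return tab.sort_values("aicc", ignore_index=True)


def model_average(
    tables: Sequence[pd.DataFrame], weights: Sequence[float]
) -> pd.DataFrame:
    """Average real-scale estimates across models.

    ``tables`` are per-model estimate grids with columns
    (param, sex, year, estimate, se); all grids must be identical.  The
    averaged estimate is sum w_i theta_i and the unconditional SE is
    sum w_i sqrt(var_i + (theta_i - theta_bar)^2) (Burnham-Anderson).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(tables):
        raise ValueError("one weight per table required")
    w = w / w.sum()
    keys = ["param", "sex", "year"]
    base = tables[0][keys].reset_index(drop=True)
    ests, ses = [], []
    for tab in tables:
        tab = tab.reset_index(drop=True)
        if not tab[keys].equals(base):
            raise ValueError("estimate grids differ between models")
        ests.append(tab["estimate"].to_numpy(dtype=float))
        ses.append(tab["se"].to_numpy(dtype=float))
    E = np.vstack(ests)
    S = np.vstack(ses)
    theta_bar = w @ E
    se_unc = np.sum(
        w[:, None] * np.sqrt(S**2 + (E - theta_bar[None, :]) ** 2), axis=0
    )
    out = base.copy()
    out["estimate"] = theta_bar
    out["se"] = se_unc
    return out


def abundance_table(fit: FitResult, data: CaptureHistory) -> pd.DataFrame:
    """Derived abundance reshaped onto the (param, sex, year) estimate grid."""
    ab = derived_abundance(fit, data, fit.design)
    return pd.DataFrame(
        {
            "param": "N",
            "sex": ab["sex"],
            "year": ab["year"],
            "estimate": ab["N_hat"],
            "se": ab["se"],
        }
    )


# ---------------------------------------------------------------------------
# candidate model sets
# ---------------------------------------------------------------------------

def printed_candidate_set() -> list[ModelStructure]:
    """The seven ranked structures of the study's model-selection table."""
    pfull = "sex*era(./time)"
    return [
        ModelStructure(".", "random", ".", pfull),
        ModelStructure("sex", "random", ".", pfull),
        ModelStructure("time", "random", ".", pfull),
        ModelStructure("sex(time/.)", "random", ".", pfull),
        ModelStructure("sex(./time)", "random", ".", pfull),
        ModelStructure("sex*time", "random", ".", pfull),
        ModelStructure("sex*time", "random", ".", "sex*era"),
    ]


def extended_candidate_set() -> list[ModelStructure]:
    """The printed seven plus plausible fill-in structures (Markovian and
    no-emigration variants, simpler detection structures).  The fill-ins are
    NOT canonical: the original candidate set of 20 was never fully listed,
    so these are documented stand-ins spanning the stated model space."""
    pfull = "sex*era(./time)"
    extras = [
        ModelStructure(".", "markovian", ".", pfull),
        ModelStructure("sex", "markovian", ".", pfull),
        ModelStructure("time", "markovian", ".", pfull),
        ModelStructure(".", "none", ".", pfull),
        ModelStructure("sex", "none", ".", pfull),
        ModelStructure(".", "random", "time", pfull),
        ModelStructure(".", "markovian", "time", pfull),
        ModelStructure(".", "random", ".", "sex*era"),
        ModelStructure("sex", "random", ".", "sex*era"),
        ModelStructure(".", "random", ".", "sex"),
        ModelStructure(".", "random", ".", "era(./time)"),
        ModelStructure(".", "random", ".", "sex*time"),
        ModelStructure(".", "random", ".", "."),
    ]
    return printed_candidate_set() + extras
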