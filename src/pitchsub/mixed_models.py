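"""Linear mixed-effect models and the population-level tests.

Two models, both with a Gaussian random intercept per bird and fitted by
maximum likelihood:

* daily pitch change: ``d'_{i−1,i} = b·ϑ_i + a·θ_i + d·φ_i + r_j``, where
  ϑ flags baseline day pairs (all birds), θ flags post-baseline pairs in
  control birds, and φ is +1/−1 for reinforcement-day pairs of high/low
  treated birds (0 otherwise).  No global intercept beyond the three
  indicators.
* singing rate: ``n_i = c + a·deaf + b·lo + d·(deaf × lo) + r_j`` on the
  relative singing rates of the last three reinforcement days.

Inference uses the residual-df Student-t convention (df = observations −
fixed effects), so a 282-observation pitch fit has df = 279.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .pitch_stats import daily_changes, daily_summaries


@dataclass
class TermFit:
    estimate: float
    se: float
    tstat: float
    df: int
    pvalue: float
    ci_low: float
    ci_high: float


@dataclass
class MixedFit:
    """Fixed-effect table plus the random-intercept variance."""

    terms: dict[str, TermFit]
    random_effect_var: float
    n_obs: int
    n_groups: int
    loglike: float
    converged: bool = True

    def __getitem__(self, name: str) -> TermFit:
        return self.terms[name]

    def to_dict(self) -> dict:
        return {
            "terms": {
                k: {
                    "estimate": t.estimate, "se": t.se, "tstat": t.tstat,
                    "df": t.df, "pvalue": t.pvalue, "ci": [t.ci_low, t.ci_high],
                }
                for k, t in self.terms.items()
            },
            "random_effect_var": self.random_effect_var,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "loglike": self.loglike,
        }


def _fit_mixed(
    endog: np.ndarray, exog: np.ndarray, groups: np.ndarray, names: list[str]
) -> MixedFit:
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("singular fixed-effect design (missing factor level?)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        result = None
        last_err: Exception | None = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                result = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError as err:  # optimizer-specific failure
                last_err = err
        if result is None:
            raise ValueError(f"mixed-model fit failed: {last_err}")
        loglike = float(result.llf)  # lazy attribute; evaluate while filtered
    k = exog.shape[1]
    df = len(endog) - k
    terms = {}
    for idx, name in enumerate(names):
        est = float(result.fe_params[idx])
        se = float(np.sqrt(np.asarray(result.cov_params())[idx, idx]))
        t = est / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), df)) if se > 0 else 1.0
        half = float(stats.t.ppf(0.975, df)) * se
        terms[name] = TermFit(est, se, t, df, p, est - half, est + half)
    # cov_re is already on the response scale in statsmodels MixedLM
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    return MixedFit(
        terms=terms,
        random_effect_var=re_var,
        n_obs=len(endog),
        n_groups=len(np.unique(groups)),
        loglike=loglike,
        converged=bool(result.converged),
    )


def pitch_change_table(table: pd.DataFrame, baseline_days: int = 5) -> pd.DataFrame:
    """Long-format daily d' changes with model indicators.

    One row per bird-day pair (i−1, i) where both days fall in the same
    phase: ``vartheta`` = 1 on baseline pairs, ``theta`` = 1 on post-baseline
    pairs of control birds, ``phi`` = ±1 on reinforcement pairs of treated
    birds (sign = target side).
    """
    meta = table.groupby("bird_id").agg(
        group=("group", "first"), target_side=("target_side", "first")
    )
    changes = daily_changes(daily_summaries(table))
    rows = []
    for row in changes.itertuples():
        group = meta.loc[row.bird_id, "group"]
        side = meta.loc[row.bird_id, "target_side"]
        in_baseline = row.day <= baseline_days
        if row.prev_day <= baseline_days and row.day > baseline_days:
            continue  # pair straddles the phase boundary
        treated = group in ("subs", "LO")
        vartheta = 1.0 if in_baseline else 0.0
        theta = 1.0 if (not in_baseline and not treated) else 0.0
        phi = 0.0
        if not in_baseline and treated:
            phi = 1.0 if side == "high" else -1.0
        rows.append(
            dict(
                bird_id=row.bird_id, day=row.day, dprime=row.dprime,
                phase="baseline" if in_baseline else "post",
                group=group, target_side=side,
                vartheta=vartheta, theta=theta, phi=phi,
            )
        )
    return pd.DataFrame.from_records(rows)


def fit_pitch_lmm(changes: pd.DataFrame) -> MixedFit:
    """Fit the three-fixed-effect daily pitch-change model.

    ``changes`` is the output of :func:`pitch_change_table` (columns
    ``dprime``, ``vartheta``, ``theta``, ``phi``, ``bird_id``).  Returns the
    fixed effects b (baseline), a (control drift), d (reinforcement), each
    with SE, t, residual df, p and 95% CI, plus the per-bird random-intercept
    variance.
    """
    exog = changes[["vartheta", "theta", "phi"]].to_numpy(dtype=float)
    endog = changes["dprime"].to_numpy(dtype=float)
    groups = changes["bird_id"].to_numpy()
    fit = _fit_mixed(endog, exog, groups, ["b", "a", "d"])
    return fit


def fit_pitch_lmm_reduced(changes: pd.DataFrame) -> MixedFit:
    """Two-fixed-effect variant: b and a collapse into one spontaneous-drift
    term active on baseline pairs and on control post pairs."""
    drift = (changes["vartheta"] + changes["theta"]).to_numpy(dtype=float)
    exog = np.column_stack([drift, changes["phi"].to_numpy(dtype=float)])
    endog = changes["dprime"].to_numpy(dtype=float)
    groups = changes["bird_id"].to_numpy()
    return _fit_mixed(endog, exog, groups, ["drift", "d"])


def singing_rate_table(
    counts: pd.DataFrame, baseline_days: int = 5, last_n: int = 3
) -> pd.DataFrame:
    """Relative singing rates for the singing-rate model.

    ``counts`` must have columns bird_id, group, day, count.  The response is
    each of the last ``last_n`` reinforcement days' count divided by the mean
    count over the last ``last_n`` baseline days.
    """
    rows = []
    for bird, sub in counts.groupby("bird_id"):
        sub = sub.sort_values("day")
        base = sub[sub["day"] <= baseline_days].tail(last_n)["count"].mean()
        stim = sub[sub["day"] > baseline_days].tail(last_n)
        group = sub["group"].iloc[0]
        deaf = group in ("subs", "unsubs", "subs_rand")
        lo = group in ("subs", "LO", "subs_rand")
        for row in stim.itertuples():
            rows.append(
                dict(
                    bird_id=bird, day=row.day, rate=row.count / base,
                    deaf=float(deaf), lo=float(lo),
                )
            )
    return pd.DataFrame.from_records(rows)


def fit_singing_lmm(rates: pd.DataFrame) -> MixedFit:
    """Fit the four-fixed-effect singing-rate model (offset, deafening,
    light-off, and their interaction)."""
    for col in ("rate", "deaf", "lo"):
        if col not in rates:
            raise ValueError(f"missing column {col!r}")
    if rates["deaf"].nunique() < 2 or rates["lo"].nunique() < 2:
        raise ValueError("missing factor level in the singing-rate design")
    exog = np.column_stack(
        [
            np.ones(len(rates)),
            rates["deaf"].to_numpy(dtype=float),
            rates["lo"].to_numpy(dtype=float),
            (rates["deaf"] * rates["lo"]).to_numpy(dtype=float),
        ]
    )
    endog = rates["rate"].to_numpy(dtype=float)
    groups = rates["bird_id"].to_numpy()
    return _fit_mixed(endog, exog, groups, ["c", "a", "b", "d"])


def per_bird_test(
    treated_changes: np.ndarray, control_changes: np.ndarray, alpha: float = 0.05
) -> dict:
    """Two-sample two-tailed pooled-variance t-test of one treated bird's
    daily pitch changes against time-matched control changes.

    Uncorrected for multiple comparisons, mirroring the per-bird screening
    convention of the paradigm.
    """
    x = np.asarray(treated_changes, dtype=float)
    y = np.asarray(control_changes, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    df = x.size + y.size - 2
    return dict(t=float(t), df=int(df), p=float(p), significant=bool(p < alpha))


def greedy_pairing(
    treated: list,
    controls: list,
    allowed: dict,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[tuple]:
    """One scarcity-first random matching of controls to treated birds.

    Controls with the fewest permissible partners are matched first, each to
    a uniformly random unused allowed treated bird.  When controls outnumber
    treated birds, every treated bird is used once and the leftover controls
    are matched with replacement to random allowed treated birds.
    ``allowed[control]`` lists that control's permissible treated partners.
    """
    for c in controls:
        if not allowed.get(c):
            raise ValueError(f"control {c!r} has no permissible partner")
    for _ in range(max_tries):
        order = sorted(controls, key=lambda c: (len(allowed[c]), rng.random()))
        used: set = set()
        pairs = []
        ok = True
        for c in order:
            free = [t for t in allowed[c] if t not in used]
            if free and len(used) < len(treated):
                t = free[int(rng.integers(len(free)))]
                used.add(t)
            else:
                # all treated already matched once: sample with replacement
                opts = list(allowed[c])
                if not opts:
                    ok = False
                    break
                if len(used) < len(treated) and not free:
                    ok = False  # bijection still required but impossible here
                    break
                t = opts[int(rng.integers(len(opts)))]
            pairs.append((t, c))
        if ok:
            return pairs
    raise ValueError("no feasible matching found (infeasible constraints?)")


def random_pairings(
    treated: list,
    controls: list,
    allowed: dict,
    test_fn,
    n_replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of random time-matched pairings whose test is significant.

    ``test_fn(pairs)`` maps a list of (treated, control) pairs to a p-value.
    Replicate r draws its pairing from substream r of the master seed.
    """
    n_sig = 0
    pvals = np.zeros(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        pairs = greedy_pairing(treated, controls, allowed, rng)
        p = float(test_fn(pairs))
        pvals[r] = p
        n_sig += p < alpha
    return dict(
        fraction_significant=n_sig / n_replicates,
        pvalues=pvals,
        n_replicates=n_replicates,
    )
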