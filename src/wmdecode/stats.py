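"""Permutation inference for within-participant designs.

All tests share one scheme: the test statistic (F or t) is computed on
the intact data and compared against a null distribution built by
shuffling labels *within each participant* (never across participants —
participants are the exchangeable-within units). One-tailed p-values are
the proportion of null statistics greater than or equal to the observed
one (ties count toward the null); the smallest achievable p is
1/n_perm. Two-tailed p-values double the smaller tail and are capped at
1, which keeps the test calibrated whichever direction the effect takes.

The repeated-measures ANOVA uses the standard fully-within-subjects
decomposition: every effect's error term is its interaction with
subjects. Permutation nulls shuffle the cell labels freely within each
participant (the exchangeability assumption for all effects).

FDR control is Benjamini-Hochberg step-up (via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    tails: str            # 'one' or 'two'
    n_perm: int


def _perm_p(observed: float, null: np.ndarray, tails: str) -> float:
    n_perm = null.size
    upper = float(np.mean(null >= observed))
    if tails == "one":
        p = upper
    elif tails == "two":
        lower = float(np.mean(null <= observed))
        p = min(2.0 * min(upper, lower), 1.0)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return max(p, 1.0 / n_perm)


def fdr_correct(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns (reject flags, adjusted p)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _powerset(items):
    return chain.from_iterable(combinations(items, r)
                               for r in range(len(items) + 1))


def rm_anova_f(data: np.ndarray, factor_names: list[str] | None = None
               ) -> dict[str, float]:
    """F statistics of a balanced fully-within-subjects ANOVA.

    ``data`` is shaped (n_subjects, levels_1, ..., levels_f) for f in
    1..3 factors. Returns an F per main effect and interaction, keyed by
    'x'.join of factor names.
    """
    data = np.asarray(data, dtype=float)
    n_factors = data.ndim - 1
    if not 1 <= n_factors <= 3:
        raise ValueError("supply 1-3 within-subject factors")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not supported")
    if factor_names is None:
        factor_names = [f"f{i + 1}" for i in range(n_factors)]
    axes = tuple(range(data.ndim))          # 0 = subjects

    # effect component for axis-subset T: sum_{S subset T} (-1)^|T\S| mean_S
    comp, ss, df = {}, {}, {}
    for T in _powerset(axes):
        total = np.zeros_like(data)
        for S in _powerset(T):
            reduce_axes = tuple(a for a in axes if a not in S)
            m = data.mean(axis=reduce_axes, keepdims=True)
            total = total + (-1) ** (len(T) - len(S)) * m
        comp[T] = total
        ss[T] = float(np.sum(total ** 2))
        df[T] = int(np.prod([data.shape[a] - 1 for a in T])) if T else 1

    out = {}
    for E in _powerset(range(1, data.ndim)):
        if not E:
            continue
        err = tuple(sorted((0,) + E))
        name = "x".join(factor_names[a - 1] for a in E)
        ms_effect = ss[E] / df[E]
        ms_error = ss[err] / df[err]
        out[name] = ms_effect / ms_error if ms_error > 0 else np.inf
    return out


def perm_rm_anova(data: np.ndarray, factor_names: list[str] | None = None,
                  n_perm: int = 1000, seed: int = 0
                  ) -> dict[str, PermutationResult]:
    """Shuffled-null repeated-measures ANOVA.

    Null distributions come from permuting the flattened cell labels
    independently within each participant on every iteration; each
    effect's p is the one-tailed proportion of null F >= observed F.
    """
    data = np.asarray(data, dtype=float)
    observed = rm_anova_f(data, factor_names)
    n_sub = data.shape[0]
    cells = data.reshape(n_sub, -1)
    rng = np.random.default_rng(seed)
    nulls = {k: np.empty(n_perm) for k in observed}
    for i in range(n_perm):
        shuffled = rng.permuted(cells, axis=1).reshape(data.shape)
        f_null = rm_anova_f(shuffled, factor_names)
        for k in observed:
            nulls[k][i] = f_null[k]
    return {k: PermutationResult(observed=observed[k], null=nulls[k],
                                 p=_perm_p(observed[k], nulls[k], "one"),
                                 tails="one", n_perm=n_perm)
            for k in observed}


# ---------------------------------------------------------------------------
# paired permutation t-test on run-wise aggregates

def _paired_t(diffs: np.ndarray) -> float:
    """One-sample t across participants on per-participant mean differences."""
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 0.0 if np.allclose(diffs.mean(), 0) else np.inf * np.sign(diffs.mean())
    return float(diffs.mean() / (sd / np.sqrt(n)))


def perm_paired_ttest(run_means_a: list[np.ndarray],
                      run_means_b: list[np.ndarray],
                      tails: str = "two", n_perm: int = 1000,
                      seed: int = 0) -> PermutationResult:
    """Paired permutation t-test with run-wise label shuffling.

    ``run_means_a`` / ``run_means_b`` hold, per participant, the paired
    run-wise values of the two conditions. The observed statistic is the
    across-participant t on participant means of the run-wise a-b
    differences; the null flips the condition labels of each run
    independently within each participant.
    """
    if len(run_means_a) != len(run_means_b) or len(run_means_a) < 2:
        raise ValueError("need paired run means for >= 2 participants")
    diffs = []
    for a, b in zip(run_means_a, run_means_b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.shape != b.shape or a.ndim != 1 or a.size < 1:
            raise ValueError("run means must be paired 1-D arrays")
        diffs.append(a - b)
    observed = _paired_t(np.array([d.mean() for d in diffs]))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        means = np.array([
            (d * rng.choice([-1.0, 1.0], size=d.size)).mean() for d in diffs])
        null[i] = _paired_t(means)
    return PermutationResult(observed=observed, null=null,
                             p=_perm_p(observed, null, tails),
                             tails=tails, n_perm=n_perm)


# ---------------------------------------------------------------------------
# shuffled-training-label fidelity null

def shuffled_label_fidelity_null(participants: list[dict],
                                 basis, n_perm: int = 1000, seed: int = 0,
                                 grid: np.ndarray | None = None
                                 ) -> PermutationResult:
    """Empirical null t for group fidelity via shuffled training labels.

    ``participants`` holds one dict per participant with keys:
    ``train_angles`` (n_trn,), ``B_trn`` (n_trn, m), ``B_tst``
    (n_tst, m), ``tst_angles`` (n_tst,) — the alignment references of
    the test trials. Each iteration permutes the training angles within
    every participant, re-estimates the encoding model, recomputes each
    participant's mean test fidelity, and takes the one-sample t across
    participants; the observed t uses intact labels and is compared
    one-tailed against the null.
    """
    from .analyses import batch_fidelity
    from .iem import estimate_weights, invert, predicted_channel_matrix

    def group_t(angle_sets) -> float:
        means = []
        for p, ang in zip(participants, angle_sets):
            model = estimate_weights(
                predicted_channel_matrix(ang, basis), p["B_trn"], basis)
            c_tst = invert(p["B_tst"], model)
            means.append(batch_fidelity(c_tst, basis, p["tst_angles"],
                                        grid=grid).mean())
        means = np.asarray(means)
        return _paired_t(means)

    observed = group_t([p["train_angles"] for p in participants])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = group_t([rng.permutation(np.asarray(p["train_angles"]))
                           for p in participants])
    return PermutationResult(observed=observed, null=null,
                             p=_perm_p(observed, null, "one"),
                             tails="one", n_perm=n_perm)


def paired_ttest_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Classic paired t (scipy) — convenience for cross-checks."""
    return float(sps.ttest_rel(a, b).statistic)
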