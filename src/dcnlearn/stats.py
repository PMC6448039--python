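"""Statistical validation of feature-learnability.

Links the classifier's behaviour to conventional statistics on the signal
features (SFs):

- *feature-pair correlations*: Pearson correlations between the five SFs,
  pooled over all trials and electrodes (redundancy screen);
- *non-significant loci*: per (animal, SF, electrode), nerve pairs whose SF
  magnitudes a linear model cannot distinguish (Tukey-adjusted pairwise
  contrast p > 0.05) — predicted sites of classifier confusion, assigned to
  one of five nerve-pair categories;
- regression of non-significant-locus counts on feature-learnability error
  (100 - learnability);
- *side dominance*: per (animal, SF, bilateral nerve pair), which body side
  evokes the significantly larger SF magnitude, at the central electrode e4
  or in the total response magnitude (TRM: |SF| summed over all 7
  electrodes);
- association of side dominance with bilateral machine-learning error at
  e4, and the correlation of dominance counts with per-SF learnability.

Dominance and loci tests operate on |SF| magnitudes by default (signed
amplitudes/slopes would invert what "greater" means); this is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .features import SF_NAMES
from .synthetic import NERVES

__all__ = [
    "LOCUS_CATEGORIES",
    "BILATERAL_PAIRS",
    "feature_pair_correlations",
    "nonsignificant_loci",
    "loci_fl_regression",
    "side_dominance",
    "e4_bilateral_ml_error",
    "dominance_error_association",
    "dominance_fl_correlation",
    "fl_error",
]

#: Bilateral (left/right same-type) nerve pairs.
BILATERAL_PAIRS = {"sural": ("LSN", "RSN"), "peroneal": ("LPN", "RPN")}

#: The five non-significant-locus categories; both cross-side/cross-type
#: pairs share one category.
LOCUS_CATEGORIES = {
    frozenset(("LSN", "RSN")): "LSNvRSN",
    frozenset(("LPN", "RPN")): "LPNvRPN",
    frozenset(("RPN", "RSN")): "RPNvRSN",
    frozenset(("LPN", "LSN")): "LPNvLSN",
    frozenset(("LPN", "RSN")): "cross",
    frozenset(("RPN", "LSN")): "cross",
}


def fl_error(feature_learnability: float) -> float:
    """Feature-learnability error, % = 100 - feature-learnability."""
    return 100.0 - feature_learnability


def feature_pair_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations for the 10 SF pairs, pooled over all trials and
    electrodes, sorted by |r| descending.

    Returns a DataFrame with columns ``feature_a, feature_b, r, p``.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 trials")
    pooled = {
        sf: np.concatenate(
            [table[f"e{e}_{sf}"].to_numpy(dtype=float) for e in range(1, 8)]
        )
        for sf in SF_NAMES
    }
    rows = []
    for a, b in combinations(SF_NAMES, 2):
        mask = np.isfinite(pooled[a]) & np.isfinite(pooled[b])
        r, p = sps.pearsonr(pooled[a][mask], pooled[b][mask])
        rows.append({"feature_a": a, "feature_b": b, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    return out.reindex(out["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def nonsignificant_loci(
    table: pd.DataFrame,
    alpha: float = 0.05,
    use_magnitude: bool = True,
    adjust: str = "tukey",
) -> pd.DataFrame:
    """Nerve pairs a linear model cannot distinguish, per animal/SF/electrode.

    For each (animal, SF, electrode) a one-way linear model of |SF| on nerve
    (4 levels) is fitted and all 6 pairwise nerve contrasts are evaluated
    with a Tukey family adjustment (``adjust='fdr'`` switches to
    Benjamini–Hochberg on the raw pairwise t-test p-values).  Contrasts with
    adjusted p > alpha are recorded as non-significant loci and assigned to
    one of the five nerve-pair categories.  A degenerate cell (all values
    identical) records a flagged locus for every pair.

    Returns a DataFrame: ``animal, sf, electrode, nerve_a, nerve_b,
    category, p, degenerate``.
    """
    rows = []
    for animal, df_a in table.groupby("animal", sort=True):
        groups_all = df_a["nerve"].to_numpy()
        for sf in SF_NAMES:
            for e in range(1, 8):
                col = f"e{e}_{sf}"
                vals = df_a[col].to_numpy(dtype=float)
                mask = np.isfinite(vals)
                vals, groups = vals[mask], groups_all[mask]
                if use_magnitude:
                    vals = np.abs(vals)
                present = sorted(set(groups), key=NERVES.index)
                if len(present) < 2 or min(
                    np.sum(groups == g) for g in present
                ) < 10:
                    raise ValueError(
                        "need >= 2 nerves with >= 10 trials each per cell"
                    )
                if np.allclose(vals, vals[0]):
                    contrasts = [
                        (a, b, 1.0, True) for a, b in combinations(present, 2)
                    ]
                elif adjust == "tukey":
                    res = pairwise_tukeyhsd(vals, groups, alpha=alpha)
                    contrasts = [
                        (str(a), str(b), float(p), False)
                        for (a, b), p in zip(
                            [
                                (res.groupsunique[i], res.groupsunique[j])
                                for i, j in zip(*np.triu_indices(len(present), 1))
                            ],
                            res.pvalues,
                        )
                    ]
                elif adjust == "fdr":
                    pairs = list(combinations(present, 2))
                    raw = [
                        sps.ttest_ind(
                            vals[groups == a], vals[groups == b]
                        ).pvalue
                        for a, b in pairs
                    ]
                    adj = multipletests(raw, method="fdr_bh")[1]
                    contrasts = [
                        (a, b, float(p), False) for (a, b), p in zip(pairs, adj)
                    ]
                else:
                    raise ValueError(f"unknown adjustment {adjust!r}")
                for a, b, p, degenerate in contrasts:
                    if p > alpha:
                        rows.append(
                            {
                                "animal": animal,
                                "sf": sf,
                                "electrode": e,
                                "nerve_a": a,
                                "nerve_b": b,
                                "category": LOCUS_CATEGORIES[frozenset((a, b))],
                                "p": p,
                                "degenerate": degenerate,
                            }
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal", "sf", "electrode", "nerve_a", "nerve_b",
            "category", "p", "degenerate",
        ],
    )


def loci_fl_regression(
    loci_counts, fl_errors
) -> tuple[float, float, float, float]:
    """Least-squares relation between non-significant-locus counts and
    feature-learnability errors (paired per SF or per electrode).

    Returns ``(pearson_r, slope, r_squared, p)`` for the regression of locus
    count on FL error.
    """
    x = np.asarray(fl_errors, dtype=float)
    y = np.asarray(loci_counts, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in counts or errors")
    fit = sps.linregress(x, y)
    return (
        float(fit.rvalue),
        float(fit.slope),
        float(fit.rvalue**2),
        float(fit.pvalue),
    )


def side_dominance(
    table: pd.DataFrame,
    scope: str = "e4",
    alpha: float = 0.05,
    use_magnitude: bool = True,
) -> pd.DataFrame:
    """Which body side evokes the larger SF for each bilateral nerve pair.

    Per (animal, SF, pair): compare |SF| between the left and right nerve's
    trials — at the central electrode (``scope='e4'``, two-group linear
    model, equivalent to a two-sample t-test) or on the total response
    magnitude (``scope='TRM'``: per-trial sum of |SF| over all 7 electrodes,
    Student's t-test).  The dominant side is the one with the significantly
    greater mean (p <= alpha), else ``'none'``.

    For N1 latency the comparison is on the latency value itself; a
    left-side "dominance" then means longer left latencies, i.e. shorter
    right-side latencies (note emitted in the ``note`` column).

    Returns ``animal, sf, scope, pair, dominant, p, mean_left, mean_right,
    note``.
    """
    if scope not in ("e4", "TRM"):
        raise ValueError("scope must be 'e4' or 'TRM'")
    rows = []
    for animal, df_a in table.groupby("animal", sort=True):
        for sf in SF_NAMES:
            if scope == "e4":
                series = df_a[f"e4_{sf}"].to_numpy(dtype=float)
            else:
                series = np.nansum(
                    np.abs(
                        df_a[[f"e{e}_{sf}" for e in range(1, 8)]].to_numpy(
                            dtype=float
                        )
                    ),
                    axis=1,
                )
            if use_magnitude and scope == "e4":
                series = np.abs(series)
            nerves = df_a["nerve"].to_numpy()
            for pair_name, (left, right) in BILATERAL_PAIRS.items():
                lv = series[nerves == left]
                rv = series[nerves == right]
                if len(lv) == 0 or len(rv) == 0:
                    raise ValueError(f"missing {pair_name} pair member")
                lv, rv = lv[np.isfinite(lv)], rv[np.isfinite(rv)]
                t = sps.ttest_ind(lv, rv)
                p = float(t.pvalue)
                if p <= alpha:
                    dominant = "L" if lv.mean() > rv.mean() else "R"
                else:
                    dominant = "none"
                rows.append(
                    {
                        "animal": animal,
                        "sf": sf,
                        "scope": scope,
                        "pair": pair_name,
                        "dominant": dominant,
                        "p": p,
                        "mean_left": float(lv.mean()),
                        "mean_right": float(rv.mean()),
                        "note": (
                            "latency dominance: greater side has the longer "
                            "latency (the other side responds earlier)"
                            if sf == "n1_latency"
                            else ""
                        ),
                    }
                )
    return pd.DataFrame(rows)


def e4_bilateral_ml_error(
    confusion: np.ndarray,
    pair: str,
    classes: tuple[str, ...] = NERVES,
) -> float:
    """Mean bilateral misclassification for one nerve pair, %.

    The mean of the two mirror off-diagonal cells of a row-normalized
    confusion matrix, e.g. (RPN classified as LPN + LPN classified as RPN)/2.
    Chance reference for a 4-class task is 25%.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.shape != (len(classes), len(classes)):
        raise ValueError("confusion shape does not match the class list")
    if not np.allclose(conf.sum(axis=1), 100.0, atol=1e-6):
        raise ValueError("confusion rows must sum to 100 (row-normalized %)")
    if pair not in BILATERAL_PAIRS:
        raise ValueError("pair must be 'sural' or 'peroneal'")
    left, right = BILATERAL_PAIRS[pair]
    i, j = classes.index(left), classes.index(right)
    return float((conf[i, j] + conf[j, i]) / 2.0)


def dominance_error_association(
    dominant, error_above_chance
) -> tuple[float, float, np.ndarray, str]:
    """Pearson chi-squared association between side dominance and bilateral
    ML error at/above chance.

    ``dominant`` and ``error_above_chance`` are matched boolean sequences
    over (animal, SF) instances: whether both bilateral pairs were side
    dominant, and whether the e4 mean ML error was >= 25%.  If any margin of
    the 2x2 table is zero the chi-squared statistic is undefined and
    Fisher's exact test is used as a flagged fallback.

    Returns ``(statistic, p, table, method)`` with method 'chi2' or
    'fisher'.
    """
    d = np.asarray(dominant, dtype=bool)
    e = np.asarray(error_above_chance, dtype=bool)
    if d.shape != e.shape:
        raise ValueError("mismatched instance counts")
    tab = np.array(
        [
            [np.sum(d & e), np.sum(d & ~e)],
            [np.sum(~d & e), np.sum(~d & ~e)],
        ],
        dtype=float,
    )
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        odds, p = sps.fisher_exact(tab)
        return float(odds), float(p), tab, "fisher"
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), float(p), tab, "chi2"


def dominance_fl_correlation(
    dominance_counts, fl_values
) -> tuple[float, float]:
    """Pearson correlation between the number of side-dominant bilateral
    pairs per SF and that SF's feature-learnability (5 paired points)."""
    x = np.asarray(dominance_counts, dtype=float)
    y = np.asarray(fl_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched per-SF observations (>= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
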