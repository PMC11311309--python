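"""Selection of key quality indicators by correlation with microbial count.

Quality attributes whose storage trajectories closely track the total
bacterial count (TBC) can stand in for plate counting when predicting shelf
life.  The selector computes the Pearson correlation between each candidate
attribute and TBC and keeps attributes with ``|r|`` above a threshold
(default 0.9).

Pairing convention
------------------
Two pairings are offered:

* ``"within_treatment"`` (default): correlate per-day replicate means with
  TBC separately within each treatment arm and summarise by the plain mean
  of the per-treatment coefficients.  This measures whether the attribute
  tracks microbial growth over storage time, independently of level
  differences between treatment arms.
* ``"pooled"``: a single correlation over all (treatment, day) mean pairs.
  Pooled coefficients are dominated by between-treatment level differences
  (an antimicrobial treatment shifts the whole TBC curve by orders of
  magnitude while quality attributes start nearly identical), so an
  attribute that tracks growth perfectly within every arm can still pool
  to a modest coefficient.  Within-treatment is therefore the default.

The sensory score is excluded from the default candidate set: it is the
acceptability response the selected indicators are meant to replace, not a
candidate quality index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import StorageDataset
from .errors import UndefinedCorrelationError

__all__ = ["pearson_r", "CorrelationReport", "select_key_indicators"]

DEFAULT_TARGET = "tbc_log_cfu_g"
DEFAULT_EXCLUDE = ("sensory",)


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length sequences.

    Raises :class:`UndefinedCorrelationError` if either input has zero
    variance, and :class:`ValueError` for sequences shorter than 3.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    return float(stats.pearsonr(xa, ya).statistic)


@dataclass
class CorrelationReport:
    """Per-attribute correlation with the target and the selected set."""

    target: str
    threshold: float
    method: str
    r: dict[str, float] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)
    n_pairs: dict[str, int] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [
            {
                "attribute": a,
                "r": self.r[a],
                "p_value": self.p_value[a],
                "significant": self.significant[a],
                "n_pairs": self.n_pairs[a],
                "selected": a in self.selected,
            }
            for a in self.r
        ]


def _r_p_from_t(r: float, n: int) -> float:
    # two-sided p for H0: rho = 0, via the t distribution with n-2 dof
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def select_key_indicators(
    dataset: StorageDataset,
    target: str = DEFAULT_TARGET,
    threshold: float = 0.9,
    method: str = "within_treatment",
    candidates: list[str] | None = None,
    alpha: float = 0.05,
) -> CorrelationReport:
    """Correlate every candidate attribute against ``target`` and select
    those with ``|r| > threshold``.

    Attributes observed at no more than half of the target's time points
    are excluded with a warning.  The significance flag (t-test at
    ``alpha``) is reported for information only; selection uses the
    threshold alone.
    """
    if method not in ("within_treatment", "pooled"):
        raise ValueError("method must be 'within_treatment' or 'pooled'")
    means = dataset.means()
    if target not in set(means["attribute"]):
        raise KeyError(f"target attribute {target!r} not present in dataset")
    if candidates is None:
        candidates = [
            a for a in dataset.attributes if a != target and a not in DEFAULT_EXCLUDE
        ]

    wide = means.pivot_table(
        index=["treatment", "time_d"], columns="attribute", values="value"
    )
    target_col = wide[target]
    n_target = target_col.notna().sum()

    report = CorrelationReport(target=target, threshold=threshold, method=method)
    for attr in candidates:
        if attr == target:
            continue
        if attr not in wide.columns:
            warnings.warn(f"attribute {attr!r} absent from dataset; skipped")
            continue
        paired = wide[[target, attr]].dropna()
        if len(paired) <= n_target / 2:
            warnings.warn(
                f"attribute {attr!r} observed at too few time points "
                f"({len(paired)}/{n_target}); excluded from selection"
            )
            continue
        if method == "pooled":
            r = pearson_r(paired[attr].to_numpy(), paired[target].to_numpy())
            n = len(paired)
        else:
            rs = []
            n = 0
            for _, sub in paired.groupby(level="treatment"):
                if len(sub) < 3:
                    continue
                rs.append(pearson_r(sub[attr].to_numpy(), sub[target].to_numpy()))
                n += len(sub)
            if not rs:
                warnings.warn(
                    f"attribute {attr!r}: no treatment with >= 3 shared points; excluded"
                )
                continue
            r = float(np.mean(rs))
        report.r[attr] = r
        report.n_pairs[attr] = n
        report.p_value[attr] = _r_p_from_t(r, n)
        report.significant[attr] = report.p_value[attr] < alpha
    report.selected = [a for a, r in report.r.items() if abs(r) > threshold]
    return report
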