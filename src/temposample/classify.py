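"""Condition classification of individual classification images.

Individual Z-scored CIs (one per participant x spatial-frequency condition)
are recoded into one of four feature spaces —

- ``time``: the 24 frame values of the time-domain CI;
- ``time_fourier``: a 12-frequency x 12-phase-bin power grid of the DFT of
  the time-domain CI (144 features);
- ``tf``: the 11 x 24 time-frequency CI, flattened (264 features);
- ``tf_fourier``: the power/phase grid of each of the 11 oscillation rows of
  the time-frequency CI (11 x 144 = 1584 features)

— then ranked by a discrimination index (between-condition variance of the
feature means over the pooled error variance) and fed one at a time, best
first, to a linear SVM evaluated with leave-one-out cross-validation. The
procedure stops when accuracy reaches 90% or the features are exhausted.
A signature map illustrates, for the selected features, how far each
condition's mean sits from the grand mean relative to the error variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ci import ZCI
from .stimuli import FRAME_RATE

__all__ = [
    "FourierFeatureGrid",
    "FeatureMatrix",
    "ClassifierResult",
    "SignatureMap",
    "REPRESENTATIONS",
    "fourier_feature_grid",
    "featureize",
    "discrimination_ranking",
    "stepwise_svm_loo",
    "binomial_vs_chance",
    "condition_signature",
]

N_PHASE_BINS = 12
GRID_FREQS = np.arange(5.0, 65.0, 5.0)  # 5..60 Hz, includes the Nyquist bin
REPRESENTATIONS = ("time", "time_fourier", "tf", "tf_fourier")


@dataclass(frozen=True)
class FourierFeatureGrid:
    """12 x 12 frequency-by-phase power grid recoding a 24-sample series.

    Each non-DC DFT frequency (5..60 Hz in 5 Hz steps at 120 Hz sampling)
    deposits its spectral power into the 30-degree phase bin containing its
    phase, so the grid sum equals the series' total non-DC power (Parseval).
    """

    power: np.ndarray  # (12 freqs, 12 phase bins)
    source_row: str = "time-domain"

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows = individual CIs (participant x condition), columns = features."""

    X: np.ndarray
    labels: np.ndarray  # condition per row
    representation: str


@dataclass(frozen=True)
class ClassifierResult:
    """Stepwise LOO-SVM trajectory and its best operating point."""

    accuracy_by_step: np.ndarray  # % correct after k features, k = 1..steps
    selected_features: np.ndarray  # ranked feature indices offered, in order
    best_accuracy: float  # %
    best_n_features: int
    p_value: float  # exact binomial vs 25% chance at the best step
    n_rows: int


@dataclass(frozen=True)
class SignatureMap:
    """Per-condition signed, normalized signature values over the selected features."""

    conditions: np.ndarray
    features: np.ndarray
    values: np.ndarray  # (n_conditions, n_features), in [-1, 1]
    display_contrast: np.ndarray  # same shape, in [0.3, 1]
    omitted: np.ndarray  # True where the raw signature value is exactly 0


# --------------------------------------------------------------------------
# Fourier feature grid


def fourier_feature_grid(series, sample_rate: float = FRAME_RATE,
                         source_row: str = "time-domain") -> FourierFeatureGrid:
    """Recode a 24-sample time course as a frequency x phase power grid.

    The DFT of the series is taken; DC is discarded; for each frequency
    5..60 Hz its power (Parseval-normalized so the grid total equals the
    series' non-DC mean-square power) lands in the 30-degree phase bin
    containing its phase. Phase bins cover [-180, 180) degrees.
    """
    x = np.asarray(getattr(series, "values", series), dtype=float).reshape(-1)
    n = x.size
    spec = np.fft.rfft(x)  # bins 0..n/2, bin spacing = sample_rate / n
    grid = np.zeros((len(GRID_FREQS), N_PHASE_BINS))
    for k in range(1, len(spec)):
        f = k * sample_rate / n
        fi = int(round(f / 5.0)) - 1
        if not (0 <= fi < len(GRID_FREQS)) or abs(f - GRID_FREQS[fi]) > 1e-9:
            continue
        # Parseval share of this bin in the mean-square of (x - mean(x))
        power = (np.abs(spec[k]) ** 2) / n**2
        if k != n // 2 or n % 2 != 0:
            power *= 2.0  # conjugate-symmetric partner (absent at Nyquist)
        phase = np.degrees(np.angle(spec[k]))
        if phase >= 180.0:
            phase -= 360.0
        pb = int(np.floor((phase + 180.0) / 30.0))
        grid[fi, min(pb, N_PHASE_BINS - 1)] += power
    return FourierFeatureGrid(power=grid, source_row=source_row)


# --------------------------------------------------------------------------
# Feature matrices


def featureize(zci_set: Sequence[ZCI], representation: str) -> FeatureMatrix:
    """Stack individual CIs into a feature matrix for one representation.

    Column ordering is deterministic: row-major for grids and maps,
    oscillation-frequency-major for ``tf_fourier`` (the grid of the 5 Hz row
    first, then 10 Hz, ...). At the default geometry the four representations
    give 24, 144, 264 and 1584 columns.
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    shapes = {z.values.shape for z in zci_set}
    if len(shapes) != 1:
        raise ValueError(f"mixed CI shapes: {shapes}")
    rows = []
    for z in zci_set:
        v = z.values
        if representation == "time":
            rows.append(v.reshape(-1))
        elif representation == "time_fourier":
            rows.append(fourier_feature_grid(v.reshape(-1)).power.reshape(-1))
        elif representation == "tf":
            rows.append(v.reshape(-1))
        else:  # tf_fourier: one grid per oscillation-frequency row
            rows.append(np.concatenate([
                fourier_feature_grid(v[r], source_row=f"row{r}").power.reshape(-1)
                for r in range(v.shape[0])
            ]))
    labels = np.asarray([z.condition for z in zci_set])
    return FeatureMatrix(X=np.vstack(rows), labels=labels, representation=representation)


# --------------------------------------------------------------------------
# Discrimination ranking


def _discrimination_index(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    conds = np.unique(labels)
    means = np.stack([X[labels == c].mean(axis=0) for c in conds])
    between = means.var(axis=0)  # population variance of the condition means
    ssw = np.zeros(X.shape[1])
    for c in conds:
        g = X[labels == c]
        ssw += ((g - g.mean(axis=0)) ** 2).sum(axis=0)
    within = ssw / (X.shape[0] - len(conds))  # pooled error variance
    D = np.empty(X.shape[1])
    both_zero = (within == 0) & (between == 0)
    inf_mask = (within == 0) & (between > 0)
    ok = within > 0
    D[ok] = between[ok] / within[ok]
    D[both_zero] = 0.0
    D[inf_mask] = np.inf
    return D


def discrimination_ranking(m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by between-condition over error variance, best first.

    Returns ``(order, index_values)``. Ties (and the all-constant D = 0 case)
    break toward the lower column index; a feature with zero error variance
    but distinct condition means ranks first (infinite index).
    """
    conds, counts = np.unique(m.labels, return_counts=True)
    if len(conds) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 conditions with >= 2 rows each")
    D = _discrimination_index(m.X, m.labels)
    order = np.argsort(-D, kind="stable")  # stable: ties keep ascending column index
    return order, D


# --------------------------------------------------------------------------
# Stepwise LOO SVM


def _loo_correct(X: np.ndarray, labels: np.ndarray, cols: np.ndarray,
                 rank_in_fold: bool, k: int) -> int:
    n = len(labels)
    correct = 0
    for i in range(n):
        tr = np.arange(n) != i
        if len(np.unique(labels[tr])) < 2:
            raise ValueError("degenerate training fold: single class")
        if rank_in_fold:
            fold_order, _ = discrimination_ranking(
                FeatureMatrix(X[tr], labels[tr], "fold")
            )
            use = fold_order[:k]
        else:
            use = cols
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(X[tr][:, use], labels[tr])
        correct += int(clf.predict(X[i : i + 1, use])[0] == labels[i])
    return correct


def stepwise_svm_loo(
    m: FeatureMatrix,
    ranking: np.ndarray | None = None,
    stop_accuracy: float = 90.0,
    rank_in_fold: bool = False,
    max_steps: int | None = None,
) -> ClassifierResult:
    """Stepwise feature introduction to a linear SVM under LOO cross-validation.

    At step k the SVM sees the k best-ranked features (features standardized
    on each training fold; C = 1). The procedure stops once LOO accuracy
    reaches ``stop_accuracy`` % or every feature has been offered. With
    ``rank_in_fold=True`` the ranking is recomputed inside each training fold
    to avoid selection leakage (the default ranks once on the full matrix).
    """
    if m.X.shape[0] < 8:
        raise ValueError("need at least 8 rows for leave-one-out classification")
    if ranking is None:
        ranking, _ = discrimination_ranking(m)
    ranking = np.asarray(ranking)
    if len(np.unique(ranking)) != m.X.shape[1]:
        raise ValueError("ranking must cover every feature column exactly once")
    n = m.X.shape[0]
    accs, best_correct = [], 0
    limit = m.X.shape[1] if max_steps is None else min(max_steps, m.X.shape[1])
    for k in range(1, limit + 1):
        correct = _loo_correct(m.X, m.labels, ranking[:k], rank_in_fold, k)
        accs.append(100.0 * correct / n)
        if correct > best_correct:
            best_correct = correct
        if accs[-1] >= stop_accuracy:
            break
    accs = np.asarray(accs)
    best_step = int(np.argmax(accs)) + 1
    best_acc = float(accs[best_step - 1])
    k_corr = int(round(best_acc / 100.0 * n))
    return ClassifierResult(
        accuracy_by_step=accs,
        selected_features=ranking[: len(accs)],
        best_accuracy=best_acc,
        best_n_features=best_step,
        p_value=binomial_vs_chance(k_corr, n),
        n_rows=n,
    )


def binomial_vs_chance(k: int, n: int, p0: float = 0.25) -> float:
    """Exact one-sided binomial tail P(X >= k) under chance performance p0."""
    if not (0 <= k <= n):
        raise ValueError(f"invalid counts k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, p0))


# --------------------------------------------------------------------------
# Condition signatures


def condition_signature(m: FeatureMatrix, selected_features) -> SignatureMap:
    """Signed, normalized signature of each condition over the selected features.

    For condition c and feature f the raw statistic is the squared deviation
    of the condition mean from the grand mean divided by the pooled error
    variance, with the sign of the deviation re-attached so the map spans
    [-1, 1] after normalization by the global maximum absolute value.
    Display contrast falls off linearly with distance from the extremes,
    floored at 0.3; exact-zero cells are flagged omitted.
    """
    sel = np.asarray(selected_features)
    if sel.size == 0:
        raise ValueError("selected_features must be non-empty")
    X = m.X[:, sel]
    conds = np.unique(m.labels)
    means = np.stack([X[m.labels == c].mean(axis=0) for c in conds])
    grand = means.mean(axis=0)
    ssw = np.zeros(X.shape[1])
    for c in conds:
        g = X[m.labels == c]
        ssw += ((g - g.mean(axis=0)) ** 2).sum(axis=0)
    err_var = ssw / (X.shape[0] - len(conds))
    if np.any(err_var == 0):
        raise ValueError("zero error variance at some selected feature")
    dev = means - grand
    raw = np.sign(dev) * dev**2 / err_var
    peak = np.abs(raw).max()
    values = raw / peak if peak > 0 else raw
    contrast = np.clip(1.0 - 0.7 * (1.0 - np.abs(values)), 0.3, 1.0)
    return SignatureMap(
        conditions=conds, features=sel, values=values,
        display_contrast=contrast, omitted=(raw == 0.0),
    )
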