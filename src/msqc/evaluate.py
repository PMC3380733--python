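"""ROC analysis against external labels, and search-time-saving arithmetic.

The operating question for a pre-search filter is: at a threshold on the
consensus probability, what fraction of the genuinely high-quality spectra
is retained (TPR) and what fraction of the poor-quality spectra is removed
(TNR = 1 - FPR)? Retention uses the >= convention, consistent with the
classifier's hard call.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .spectra import HIGH, POOR

ROC_COLUMNS = ["threshold", "tpr", "fpr", "tnr"]


def _aligned(scores: Mapping[str, float], labels: Mapping[str, str]):
    ids = list(scores)
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValueError(f"{len(missing)} scored spectra have no label, e.g. {missing[:3]}")
    y = np.array([labels[i] == HIGH for i in ids])
    s = np.array([scores[i] for i in ids], dtype=float)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class; ROC analysis needs both")
    return s, y


def roc_curve(scores: Mapping[str, float], labels: Mapping[str, str]) -> pd.DataFrame:
    """ROC points for thresholding p_high, one per distinct threshold.

    The threshold grid is {0} ∪ {observed scores} ∪ {just above max}, so the
    curve always contains the all-retained and none-retained corners. A
    spectrum is retained when its score is >= the threshold.
    """
    s, y = _aligned(scores, labels)
    thresholds = np.unique(np.concatenate(([0.0], s, [np.nextafter(s.max(), np.inf)])))
    n_high = int(y.sum())
    n_poor = int((~y).sum())
    rows = []
    for t in thresholds:
        kept = s >= t
        rows.append((t, (kept & y).sum() / n_high, (kept & ~y).sum() / n_poor))
    df = pd.DataFrame(rows, columns=["threshold", "tpr", "fpr"])
    df["tnr"] = 1.0 - df["fpr"]
    return df


def roc_auc(curve: pd.DataFrame) -> float:
    """Area under the (fpr, tpr) curve by the trapezoid rule."""
    pts = curve.sort_values(["fpr", "tpr"])
    return float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))


def tnr_at_tpr(curve: pd.DataFrame, tpr_floor: float) -> float:
    """Best poor-spectrum removal rate achievable while retaining at least
    ``tpr_floor`` of the high-quality spectra."""
    if curve.empty:
        raise ValueError("empty ROC curve")
    eligible = curve[curve["tpr"] >= tpr_floor]
    if eligible.empty:
        raise ValueError(f"no ROC point reaches tpr >= {tpr_floor}")
    return float(eligible["tnr"].max())


def search_savings(n_high_called: int, n_total: int) -> float:
    """Fraction of database-search time saved by searching only the spectra
    called high quality: 1 - n_high_called / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_high_called <= n_total:
        raise ValueError("n_high_called must lie in [0, n_total]")
    return 1.0 - n_high_called / n_total


def plot_roc(curve: pd.DataFrame, path, title: str = "Consensus quality ROC") -> None:
    """Write a PNG of the ROC curve (FPR vs TPR, chance diagonal shown)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = curve.sort_values(["fpr", "tpr"])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(pts["fpr"], pts["tpr"], marker=".", lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
    ax.set_xlabel("False positive rate (poor retained)")
    ax.set_ylabel("True positive rate (high retained)")
    ax.set_title(title)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
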