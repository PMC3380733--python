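"""The ten spectral quality features.

Each feature is a scalar summary of one spectrum, designed so that larger
values indicate a spectrum more likely to be a real peptide fragmentation
pattern (and hence worth database searching):

====  =========================================================  =========
 f    meaning                                                    units
====  =========================================================  =========
 f1   total normalized intensity of complementary peak pairs     fraction
 f2   uncharged precursor mass                                   Da
 f3   # peak pairs differing by an amino-acid residue mass       count
 f4   mean gap between neighbouring peaks                        Da
 f5   Good-Diff fraction: normalized intensity of residue pairs  fraction
 f6   # complementary peak pairs                                 count
 f7   # pairs differing by a water or ammonia loss               count
 f8   fraction of peaks above 1% of total intensity              fraction
 f9   standard deviation of neighbour gaps                       Da
 f10  # pairs differing by a CO or NH group (a-/z-ion support)   count
====  =========================================================  =========

All peaks are treated as singly charged. Pair comparisons use an absolute
tolerance (default 0.5 Da, suitable for low-resolution ion-trap data). Two
peaks are *complementary* when their m/z values sum to the precursor-derived
pair-sum target; by default that target is the uncharged precursor mass
(= f2), with the singly-protonated and b/y-ion conventions available via
:class:`MassConstants.pair_sum_convention`.

Pair searches run on the sorted peak list with ``searchsorted`` windows and
prefix sums; the unit tests pin them to a brute-force double loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mass as _pymass

from .spectra import Spectrum

logger = logging.getLogger(__name__)

FEATURE_NAMES = [f"f{i}" for i in range(1, 11)]

#: Monoisotopic residue masses of the 20 proteinogenic amino acids, Da.
#: Not all are unique (Leu/Ile coincide; Gln/Lys differ by 0.036 Da).
STANDARD_RESIDUES: dict[str, float] = {
    aa: _pymass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

PROTON: float = _pymass.nist_mass["H+"][0][0]
WATER: float = _pymass.calculate_mass(formula="H2O")
AMMONIA: float = _pymass.calculate_mass(formula="NH3")
CO_GROUP: float = _pymass.calculate_mass(formula="CO")
NH_GROUP: float = _pymass.calculate_mass(formula="NH")


@dataclass(frozen=True)
class MassConstants:
    """Mass table and matching tolerance shared by all pair-based features."""

    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(STANDARD_RESIDUES))
    water: float = WATER
    ammonia: float = AMMONIA
    co_group: float = CO_GROUP
    nh_group: float = NH_GROUP
    proton: float = PROTON
    tolerance: float = 0.5
    #: "neutral": target = uncharged precursor mass (default);
    #: "protonated": target = precursor_mz*z - (z-1)*proton;
    #: "by_pair": target = uncharged mass + 2*proton (singly charged b+y sum).
    pair_sum_convention: str = "neutral"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")
        if self.pair_sum_convention not in ("neutral", "protonated", "by_pair"):
            raise ValueError(
                f"unknown pair_sum_convention {self.pair_sum_convention!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MassConstants":
        """Load overrides (tolerance, residue masses, convention...) from YAML."""
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        base = cls()
        if "residue_masses" in data:
            merged = dict(base.residue_masses)
            merged.update({str(k): float(v) for k, v in data.pop("residue_masses").items()})
            data["residue_masses"] = merged
        return replace(base, **data)

    def pair_sum_target(self, spectrum: Spectrum) -> float:
        """The m/z-sum value at which two peaks are complementary."""
        z = spectrum.precursor_charge
        neutral = spectrum.precursor_mz * z - z * self.proton
        if self.pair_sum_convention == "neutral":
            return neutral
        if self.pair_sum_convention == "protonated":
            return spectrum.precursor_mz * z - (z - 1) * self.proton
        return neutral + 2 * self.proton


DEFAULT_CONSTANTS = MassConstants()


# ---------------------------------------------------------------------------
# window helpers (sorted m/z arrays, inclusive tolerance)

def _merge_intervals(targets: Iterable[float], tol: float) -> list[tuple[float, float]]:
    ivals = sorted((t - tol, t + tol) for t in targets)
    merged: list[tuple[float, float]] = []
    for lo, hi in ivals:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _diff_pair_stats(mz: np.ndarray, weights: np.ndarray | None,
                     targets: Iterable[float], tol: float) -> tuple[int, float]:
    """Count unordered pairs whose m/z difference falls in the union of the
    ±tol windows around `targets`; optionally sum weight(x)+weight(y) over
    those pairs. A pair matching several targets counts once."""
    count = 0
    wsum = 0.0
    idx = np.arange(mz.size)
    cumw = np.concatenate(([0.0], np.cumsum(weights))) if weights is not None else None
    for lo, hi in _merge_intervals(targets, tol):
        left = np.searchsorted(mz, mz + lo, side="left")
        right = np.searchsorted(mz, mz + hi, side="right")
        left = np.maximum(left, idx + 1)  # partner strictly above: each pair once
        n_in = np.maximum(right - left, 0)
        count += int(n_in.sum())
        if cumw is not None:
            wsum += float((n_in * weights).sum())
            wsum += float((cumw[np.maximum(right, left)] - cumw[left]).sum())
    return count, wsum


def _sum_pair_stats(mz: np.ndarray, weights: np.ndarray | None,
                    target: float, tol: float) -> tuple[int, float]:
    """Count unordered pairs (x < y) with mz(x)+mz(y) within ±tol of `target`;
    optionally sum weight(x)+weight(y) over them."""
    n = mz.size
    idx = np.arange(n)
    left = np.searchsorted(mz, target - mz - tol, side="left")
    right = np.searchsorted(mz, target - mz + tol, side="right")
    left = np.maximum(left, idx + 1)  # partner strictly after x: each pair once
    n_in = np.maximum(right - left, 0)
    count = int(n_in.sum())
    wsum = 0.0
    if weights is not None:
        cumw = np.concatenate(([0.0], np.cumsum(weights)))
        take = n_in > 0
        wsum = float((n_in * weights).sum())
        wsum += float((cumw[np.maximum(right, left)[take]] - cumw[left[take]]).sum())
    return count, wsum


def _require_pairs(spectrum: Spectrum, what: str) -> bool:
    if len(spectrum) < 2:
        logger.warning("spectrum %s: <2 peaks, %s degenerates to 0", spectrum.id, what)
        return False
    return True


# ---------------------------------------------------------------------------
# the features

def normalized_intensities(spectrum: Spectrum) -> np.ndarray:
    """Per-peak intensity divided by the spectrum's total intensity (sums to 1)."""
    inten = spectrum.intensity
    total = inten.sum()
    if inten.size == 0 or total <= 0:
        raise ValueError(f"spectrum {spectrum.id}: no positive-intensity peaks")
    return inten / total


def f1_complement_intensity(spectrum: Spectrum,
                            c: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Total normalized intensity carried by complementary peak pairs, capped at 1."""
    if not _require_pairs(spectrum, "f1"):
        return 0.0
    _, wsum = _sum_pair_stats(spectrum.mz, normalized_intensities(spectrum),
                              c.pair_sum_target(spectrum), c.tolerance)
    return min(wsum, 1.0)


def f2_uncharged_precursor_mass(spectrum: Spectrum,
                                c: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Neutral precursor mass: precursor_mz * z - z * proton."""
    z = spectrum.precursor_charge
    return spectrum.precursor_mz * z - z * c.proton


def f3_aa_difference_count(spectrum: Spectrum,
                           c: MassConstants = DEFAULT_CONSTANTS) -> int:
    """Number of peak pairs whose m/z difference matches a residue mass."""
    if not _require_pairs(spectrum, "f3"):
        return 0
    count, _ = _diff_pair_stats(spectrum.mz, None,
                                c.residue_masses.values(), c.tolerance)
    return count


def f4_mean_delta_mass(spectrum: Spectrum) -> float:
    """Mean m/z gap between neighbouring peaks (low for over-dense spectra)."""
    if not _require_pairs(spectrum, "f4"):
        return 0.0
    return float(np.diff(spectrum.mz).mean())


def f5_good_diff_fraction(spectrum: Spectrum,
                          c: MassConstants = DEFAULT_CONSTANTS) -> float:
    """Good-Diff fraction: sum of NormI(x)+NormI(y) over residue-mass pairs."""
    if not _require_pairs(spectrum, "f5"):
        return 0.0
    _, wsum = _diff_pair_stats(spectrum.mz, normalized_intensities(spectrum),
                               c.residue_masses.values(), c.tolerance)
    return wsum


def f6_complementary_pair_count(spectrum: Spectrum,
                                c: MassConstants = DEFAULT_CONSTANTS) -> int:
    """Number of peak pairs summing to the precursor pair-sum target."""
    if not _require_pairs(spectrum, "f6"):
        return 0
    count, _ = _sum_pair_stats(spectrum.mz, None,
                               c.pair_sum_target(spectrum), c.tolerance)
    return count


def f7_neutral_loss_pair_count(spectrum: Spectrum,
                               c: MassConstants = DEFAULT_CONSTANTS) -> int:
    """Number of peak pairs differing by a water or ammonia molecule."""
    if not _require_pairs(spectrum, "f7"):
        return 0
    count, _ = _diff_pair_stats(spectrum.mz, None, (c.water, c.ammonia), c.tolerance)
    return count


def f8_intense_peak_ratio(spectrum: Spectrum) -> float:
    """Fraction of peaks whose intensity exceeds 1% of the total intensity."""
    inten = spectrum.intensity
    if inten.size == 0:
        raise ValueError(f"spectrum {spectrum.id}: empty peak list")
    return float((inten > 0.01 * inten.sum()).mean())


def f9_delta_mass_std(spectrum: Spectrum) -> float:
    """Sample standard deviation of neighbour m/z gaps (0 with <3 peaks)."""
    if len(spectrum) < 3:
        logger.warning("spectrum %s: <3 peaks, f9 degenerates to 0", spectrum.id)
        return 0.0
    return float(np.diff(spectrum.mz).std(ddof=1))


def f10_support_ion_pair_count(spectrum: Spectrum,
                               c: MassConstants = DEFAULT_CONSTANTS) -> int:
    """Number of peak pairs differing by CO or NH (a-/z-ion evidence)."""
    if not _require_pairs(spectrum, "f10"):
        return 0
    count, _ = _diff_pair_stats(spectrum.mz, None,
                                (c.co_group, c.nh_group), c.tolerance)
    return count


def feature_vector(spectrum: Spectrum,
                   c: MassConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """The ten features of one spectrum, in the fixed order f1..f10."""
    return np.array([
        f1_complement_intensity(spectrum, c),
        f2_uncharged_precursor_mass(spectrum, c),
        f3_aa_difference_count(spectrum, c),
        f4_mean_delta_mass(spectrum),
        f5_good_diff_fraction(spectrum, c),
        f6_complementary_pair_count(spectrum, c),
        f7_neutral_loss_pair_count(spectrum, c),
        f8_intense_peak_ratio(spectrum),
        f9_delta_mass_std(spectrum),
        f10_support_ion_pair_count(spectrum, c),
    ], dtype=float)


def compute_feature_matrix(spectra: Sequence[Spectrum],
                           c: MassConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Feature table with one row per spectrum (index = spectrum id)."""
    rows = [feature_vector(s, c) for s in spectra]
    index = pd.Index([s.id for s in spectra], name="id")
    data = np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    return pd.DataFrame(data, index=index, columns=FEATURE_NAMES)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
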