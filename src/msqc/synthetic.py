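"""Labelled synthetic MS/MS spectra with a known high/poor ground truth.

High-quality spectra emulate the fragmentation pattern of a tryptic-size
random peptide measured on a low-resolution instrument as singly charged
ions: a b-ion ladder (so neighbouring same-series ions differ by residue
masses), the complementary y-series partner of each b-ion (placed at
pair-sum-target minus b, so planted complementary pairs are detectable
under the configured convention), water/ammonia neutral-loss satellites,
random ion drop-out, Gaussian m/z jitter and low-intensity noise peaks.

Poor-quality spectra are pure chemical noise: uniform random m/z positions,
a haystack of small intensities with a few dominant spikes, and a low
precursor mass.

All randomness flows from the single seed in :class:`SimConfig` through one
`numpy` generator; the same config always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import DEFAULT_CONSTANTS, MassConstants
from .spectra import HIGH, POOR, Spectrum, write_labels, write_mgf

_MIN_MZ = 50.0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate a low-resolution ion-trap run
    with the heavy class imbalance (~95% poor) typical of real datasets."""

    n_high: int = 50
    n_poor: int = 950
    peptide_length_range: tuple[int, int] = (8, 15)
    noise_peaks_range: tuple[int, int] = (5, 40)
    poor_peaks_range: tuple[int, int] = (20, 70)
    #: acquisition window for pure-noise peaks; noise is precursor-independent,
    #: so poor spectra span the instrument's full scan range
    scan_range: tuple[float, float] = (100.0, 1700.0)
    #: (median, sigma-of-log) of the lognormal fragment intensity
    fragment_intensity: tuple[float, float] = (100.0, 0.4)
    #: (median, sigma-of-log) of the lognormal noise intensity
    noise_intensity: tuple[float, float] = (6.0, 0.6)
    neutral_loss_prob: float = 0.3
    complement_drop_prob: float = 0.2
    mz_jitter_sd: float = 0.05
    min_peaks: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_poor < 0:
            raise ValueError("spectrum counts must be non-negative")
        for p in (self.neutral_loss_prob, self.complement_drop_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal(rng: np.random.Generator, params: tuple[float, float], size: int) -> np.ndarray:
    median, sigma = params
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)


def simulate_high(config: SimConfig, rng: np.random.Generator | None = None,
                  spectrum_id: str = "sim_high",
                  constants: MassConstants = DEFAULT_CONSTANTS) -> Spectrum:
    """One high-quality spectrum: b/y ladders of a random peptide plus noise."""
    rng = config.rng() if rng is None else rng
    lo, hi = config.peptide_length_range
    length = int(rng.integers(lo, hi + 1))
    residues = rng.choice(list(constants.residue_masses.values()), size=length)
    neutral_mass = float(residues.sum() + constants.water)
    precursor_mz = neutral_mass + constants.proton
    spectrum_stub = Spectrum(spectrum_id, precursor_mz, 1, [])
    target = constants.pair_sum_target(spectrum_stub)

    # b-ladder including the full-length acylium ion, and the complementary
    # partner of each backbone cleavage
    b_ions = np.cumsum(residues) + constants.proton
    y_ions = target - b_ions[:-1]
    ions = np.concatenate([b_ions, y_ions])
    ions = ions[ions >= _MIN_MZ]
    keep = rng.random(ions.size) >= config.complement_drop_prob
    if keep.sum() < 2:  # never emit an empty ladder
        keep[:] = True
    ions = ions[keep]

    losses = []
    for ion in ions:
        if rng.random() < config.neutral_loss_prob:
            delta = constants.water if rng.random() < 0.5 else constants.ammonia
            if ion - delta >= _MIN_MZ:
                losses.append(ion - delta)
    losses = np.asarray(losses, dtype=float)

    n_noise = int(rng.integers(config.noise_peaks_range[0],
                               config.noise_peaks_range[1] + 1))
    noise_mz = rng.uniform(_MIN_MZ + 50, max(neutral_mass, 500.0), size=n_noise)

    signal_mz = np.concatenate([ions, losses])
    signal_mz = signal_mz + rng.normal(0.0, config.mz_jitter_sd, size=signal_mz.size)
    mz = np.concatenate([signal_mz, noise_mz])
    intensity = np.concatenate([
        _lognormal(rng, config.fragment_intensity, ions.size),
        0.5 * _lognormal(rng, config.fragment_intensity, losses.size),
        _lognormal(rng, config.noise_intensity, n_noise),
    ])
    return Spectrum.from_arrays(spectrum_id, precursor_mz, 1, mz, intensity)


def simulate_poor(config: SimConfig, rng: np.random.Generator | None = None,
                  spectrum_id: str = "sim_poor",
                  constants: MassConstants = DEFAULT_CONSTANTS) -> Spectrum:
    """One poor-quality spectrum: random noise with a low-mass precursor."""
    rng = config.rng() if rng is None else rng
    neutral_mass = float(rng.uniform(250.0, 900.0))
    precursor_mz = neutral_mass + constants.proton
    n_peaks = max(config.min_peaks,
                  int(rng.integers(config.poor_peaks_range[0],
                                   config.poor_peaks_range[1] + 1)))
    mz = rng.uniform(config.scan_range[0], config.scan_range[1], size=n_peaks)
    # a haystack of small peaks with a few dominant chemical-noise spikes
    intensity = _lognormal(rng, config.noise_intensity, n_peaks)
    n_spikes = min(n_peaks, int(rng.integers(1, 5)))
    spike_at = rng.choice(n_peaks, size=n_spikes, replace=False)
    intensity[spike_at] = _lognormal(rng, (25 * config.noise_intensity[0], 0.5), n_spikes)
    return Spectrum.from_arrays(spectrum_id, precursor_mz, 1, mz, intensity)


def simulate_dataset(config: SimConfig,
                     constants: MassConstants = DEFAULT_CONSTANTS
                     ) -> tuple[list[Spectrum], dict[str, str]]:
    """A shuffled labelled dataset of n_high + n_poor spectra.

    Ids are positional (``sim_00001`` ...) and assigned after shuffling, so
    neither id text nor file order leaks the label.
    """
    if config.n_high + config.n_poor < 2:
        raise ValueError("need at least 2 spectra in total")
    rng = config.rng()
    entries: list[tuple[Spectrum, str]] = []
    for _ in range(config.n_high):
        entries.append((simulate_high(config, rng, constants=constants), HIGH))
    for _ in range(config.n_poor):
        entries.append((simulate_poor(config, rng, constants=constants), POOR))
    order = rng.permutation(len(entries))
    spectra: list[Spectrum] = []
    labels: dict[str, str] = {}
    for pos, idx in enumerate(order, start=1):
        spectrum, label = entries[idx]
        spectrum.id = f"sim_{pos:05d}"
        spectra.append(spectrum)
        labels[spectrum.id] = label
    return spectra, labels


def write_dataset(spectra: list[Spectrum], labels: dict[str, str],
                  out_dir: str | Path) -> tuple[Path, Path]:
    """Write the dataset as MGF + label TSV; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mgf_path = out_dir / "spectra.mgf"
    label_path = out_dir / "labels.tsv"
    write_mgf(spectra, mgf_path)
    write_labels(labels, label_path)
    return mgf_path, label_path
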