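"""Peak-list data model and MGF / label-table I/O.

The internal representation of one MS/MS scan is :class:`Spectrum`: an id,
the precursor m/z and assumed charge, and a peak list kept strictly sorted
by ascending m/z. Reading canonicalizes every spectrum: peaks are sorted,
exact duplicate m/z values are merged (summed intensity) and zero-intensity
peaks are dropped, so downstream pair counting always sees distinct,
informative peaks.

MGF (Mascot Generic Format) is the on-disk peak-list format; parsing of the
individual ``BEGIN IONS``/``END IONS`` blocks is delegated to
:mod:`pyteomics.mgf`. The file is split into blocks first so that a single
malformed block is rejected (with a logged reason) without losing the rest
of the file.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

HIGH = "high"
POOR = "poor"

_LABEL_ALIASES = {
    "high": HIGH,
    "h": HIGH,
    "1": HIGH,
    "good": HIGH,
    "poor": POOR,
    "p": POOR,
    "2": POOR,
    "bad": POOR,
    "low": POOR,
}


@dataclass(frozen=True)
class Peak:
    """A single fragment peak: m/z in Thomson, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass
class Spectrum:
    """One tandem mass spectrum with a canonical (sorted, distinct-m/z) peak list."""

    id: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        if int(self.precursor_charge) < 1:
            raise ValueError(f"precursor charge must be >= 1, got {self.precursor_charge}")
        self.precursor_charge = int(self.precursor_charge)
        mz = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mz, mz[1:])):
            raise ValueError(f"spectrum {self.id!r}: peaks must be strictly sorted by m/z")

    @classmethod
    def from_arrays(
        cls,
        id: str,
        precursor_mz: float,
        precursor_charge: int,
        mz: Sequence[float],
        intensity: Sequence[float],
    ) -> "Spectrum":
        """Build a canonical spectrum from raw arrays.

        Sorts by m/z, merges exact duplicate m/z values (summing intensity)
        and drops zero-intensity peaks.
        """
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays must have the same length")
        if mz.size:
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            uniq, inverse = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
            keep = inten > 0
            mz, inten = mz[keep], inten[keep]
        peaks = [Peak(m, i) for m, i in zip(mz, inten)]
        return cls(id=id, precursor_mz=float(precursor_mz),
                   precursor_charge=int(precursor_charge), peaks=peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


def _split_blocks(text: str) -> Iterable[str]:
    """Yield the raw text of each BEGIN IONS / END IONS block."""
    lines = text.splitlines()
    block: list[str] | None = None
    for line in lines:
        stripped = line.strip()
        if stripped.upper() == "BEGIN IONS":
            block = [line]
        elif stripped.upper() == "END IONS":
            if block is not None:
                block.append(line)
                yield "\n".join(block) + "\n"
            block = None
        elif block is not None:
            block.append(line)


def _parse_charge(raw) -> int | None:
    """First listed charge as a positive int, or None if absent."""
    if raw is None:
        return None
    if isinstance(raw, (list, tuple)):
        if not raw:
            return None
        if len(raw) > 1:
            logger.warning("multiple charges listed (%s); taking the first", raw)
        raw = raw[0]
    return abs(int(raw))


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of canonical :class:`Spectrum` records.

    Malformed blocks (no PEPMASS, non-numeric peak lines) are rejected
    individually with a logged reason. A spectrum with no CHARGE header
    defaults to charge 1 with a warning. Ids come from TITLE, falling back
    to ``<filename>#<ordinal>``.
    """
    path = Path(path)
    text = path.read_text()
    spectra: list[Spectrum] = []
    n_rejected = 0
    for ordinal, block in enumerate(_split_blocks(text), start=1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                entry = next(_mgf.read(io.StringIO(block), use_index=False), None)
            if entry is None:
                raise ValueError("empty block")
            params = entry["params"]
            if "pepmass" not in params:
                raise ValueError("missing PEPMASS")
            pepmass = params["pepmass"]
            precursor_mz = float(pepmass[0] if isinstance(pepmass, (list, tuple)) else pepmass)
            charge = _parse_charge(params.get("charge"))
            if charge is None:
                logger.warning("block %d (%s): no CHARGE header, assuming 1+",
                               ordinal, params.get("title", "untitled"))
                charge = 1
            sid = str(params.get("title") or f"{path.name}#{ordinal}")
            spectra.append(Spectrum.from_arrays(
                sid, precursor_mz, charge, entry["m/z array"], entry["intensity array"]))
        except Exception as exc:  # per-block isolation: keep reading the file
            n_rejected += 1
            logger.warning("rejected MGF block %d in %s: %s", ordinal, path.name, exc)
    logger.info("read %d spectra from %s (%d block(s) rejected)",
                len(spectra), path, n_rejected)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to an MGF file; inverse of :func:`read_mgf` up to float format."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {"title": s.id, "pepmass": s.precursor_mz, "charge": s.precursor_charge},
        }
        for s in spectra
    ]
    with open(path, "w") as handle:
        _mgf.write(entries, handle)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) table into ``{id: "high"|"poor"}``.

    Accepts comma or tab delimiters and the aliases H/P (case-insensitive).
    Duplicate ids and unrecognized label tokens are errors.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#",
                     dtype=str, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path}: expected two columns (id, label)")
    df = df.iloc[:, :2]
    df.columns = ["id", "label"]
    if df.iloc[0].str.lower().tolist() == ["id", "label"]:
        df = df.iloc[1:]
    ids = df["id"].str.strip()
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate spectrum id(s) in label file: {dupes}")
    table: dict[str, str] = {}
    for sid, token in zip(ids, df["label"].str.strip().str.lower()):
        if token not in _LABEL_ALIASES:
            raise ValueError(f"unknown label token {token!r} for id {sid!r}")
        table[sid] = _LABEL_ALIASES[token]
    return table


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    """Write an id → high/poor table as TSV."""
    pd.DataFrame({"id": list(labels), "label": list(labels.values())}).to_csv(
        path, sep="\t", index=False, header=False)
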