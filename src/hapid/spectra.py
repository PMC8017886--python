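"""MS/MS spectrum container and MGF input/output (via pyteomics)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from pyteomics import mgf as _mgf

from .constants import PROTON


@dataclass
class SpectrumRecord:
    """One MS/MS spectrum: precursor, charge and a peak list sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(f"spectrum {self.spectrum_id}: ragged peak list")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if not 1 <= self.charge <= 7:
            raise ValueError(
                f"spectrum {self.spectrum_id}: charge {self.charge} outside [1, 7]"
            )

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass implied by precursor m/z and charge."""
        return self.precursor_mz * self.charge - self.charge * PROTON


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF file; charge defaults to 2 when the block omits it."""
    out: list[SpectrumRecord] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 2
            pepmass = params["pepmass"]
            out.append(
                SpectrumRecord(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


def read_mzml(path: str | Path) -> list[SpectrumRecord]:
    """Thin mzML adapter (via pyteomics): MS2 scans only; spectra without
    a selected precursor are skipped."""
    from pyteomics import mzml as _mzml

    out: list[SpectrumRecord] = []
    with _mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            try:
                ion = entry["precursorList"]["precursor"][0][
                    "selectedIonList"
                ]["selectedIon"][0]
            except (KeyError, IndexError):
                continue
            out.append(
                SpectrumRecord(
                    spectrum_id=str(entry.get("id", f"scan_{len(out)}")),
                    precursor_mz=float(ion["selected ion m/z"]),
                    charge=int(ion.get("charge state", 2)),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


def write_mgf(spectra: Iterable[SpectrumRecord], path: str | Path) -> None:
    """Write spectra as MGF with fixed formatting (stable across runs)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")
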