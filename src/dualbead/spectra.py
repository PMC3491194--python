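"""Mass-spectrum container and plain-text XY input/output.

A profile is a single MALDI-TOF acquisition: an m/z axis with one
intensity per grid point, tagged with the bead platform (``WCX`` or
``RPC18``), the serum sample it came from and the technical replicate
index (each sample is spotted in quadruplicate per platform).

Spectra are exchanged on disk as two-column whitespace-delimited text
(.dat), one file per spectrum, together with a TSV manifest listing
sample, class label, platform, replicate and file path.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "read_xy",
    "write_xy",
    "read_manifest",
    "write_manifest",
]


class Spectrum:
    """One acquired or simulated profile.

    Parameters
    ----------
    mz : array-like
        Strictly increasing m/z axis in Da.
    intensity : array-like
        Intensities on the same grid, arbitrary units, finite.
    platform_id, sample_id, replicate_index :
        Identity of the spectrum within a cohort.

    Notes
    -----
    Simulated spectra share one nominal acquisition grid per platform;
    a per-spectrum mass-calibration factor relabels the axis without
    copying it.  Use :meth:`on_grid` for that representation — the
    public :attr:`mz` property is identical in both cases.
    """

    __slots__ = ("intensity", "platform_id", "sample_id", "replicate_index",
                 "_mz", "_grid", "_factor")

    def __init__(self, mz, intensity, *, platform_id="", sample_id="",
                 replicate_index=1, check=True):
        intensity = np.asarray(intensity, dtype=float)
        mz = np.asarray(mz, dtype=float)
        if mz.ndim != 1 or mz.shape != intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        self._mz = mz
        self._grid = None
        self._factor = 1.0
        self.intensity = intensity
        self.platform_id = platform_id
        self.sample_id = sample_id
        self.replicate_index = int(replicate_index)
        if check:
            self.validate()

    @classmethod
    def on_grid(cls, grid, intensity, *, drift_factor=1.0, platform_id="",
                sample_id="", replicate_index=1):
        """Build a spectrum on a shared nominal grid with a calibration factor.

        The effective m/z axis is ``grid * drift_factor``; the grid array is
        referenced, not copied, so large simulated cohorts share it.
        """
        self = cls.__new__(cls)
        self._mz = None
        self._grid = np.asarray(grid, dtype=float)
        self._factor = float(drift_factor)
        self.intensity = np.asarray(intensity, dtype=float)
        if self.intensity.shape != self._grid.shape:
            raise ValueError("intensity length must match grid length")
        self.platform_id = platform_id
        self.sample_id = sample_id
        self.replicate_index = int(replicate_index)
        return self

    @property
    def mz(self) -> np.ndarray:
        if self._mz is not None:
            return self._mz
        return self._grid * self._factor

    @property
    def drift_factor(self) -> float:
        """Calibration relabelling factor of the axis (1.0 for measured data)."""
        return self._factor

    def __len__(self) -> int:
        return self.intensity.shape[0]

    @property
    def spectrum_id(self) -> str:
        return f"{self.sample_id}_{self.platform_id}_r{self.replicate_index}"

    def tic(self) -> float:
        """Total ion current: the sum of all intensities."""
        return float(self.intensity.sum())

    def validate(self) -> None:
        mz = self.mz
        if len(mz) >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def with_intensity(self, intensity) -> "Spectrum":
        """Copy with a new intensity vector on the same axis."""
        if self._mz is None:
            s = Spectrum.on_grid(self._grid, intensity,
                                 drift_factor=self._factor,
                                 platform_id=self.platform_id,
                                 sample_id=self.sample_id,
                                 replicate_index=self.replicate_index)
            return s
        return Spectrum(self._mz, intensity, platform_id=self.platform_id,
                        sample_id=self.sample_id,
                        replicate_index=self.replicate_index, check=False)

    def with_mz(self, mz) -> "Spectrum":
        """Copy with a new (e.g. recalibrated) m/z axis."""
        return Spectrum(mz, self.intensity, platform_id=self.platform_id,
                        sample_id=self.sample_id,
                        replicate_index=self.replicate_index, check=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Spectrum({self.spectrum_id}, n={len(self)}, "
                f"mz=[{self.mz[0]:.2f}..{self.mz[-1]:.2f}])")


def write_xy(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column whitespace-delimited XY text."""
    arr = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, arr, fmt="%.5f %.6g")


def read_xy(path, *, platform_id="", sample_id="", replicate_index=1) -> Spectrum:
    """Read a two-column XY text file (m/z, intensity) into a Spectrum."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    return Spectrum(arr[:, 0], arr[:, 1], platform_id=platform_id,
                    sample_id=sample_id, replicate_index=replicate_index)


MANIFEST_COLUMNS = ["sample_id", "label", "platform", "replicate", "path"]


def write_manifest(rows: pd.DataFrame, path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    rows.loc[:, MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "label": str,
                                            "platform": str, "path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns: {missing}")
    return df


def load_manifest_spectra(manifest: pd.DataFrame, base_dir=None):
    """Yield spectra listed in a manifest, resolving relative paths.

    Raises ``FileNotFoundError`` naming the offending path, so a broken
    manifest aborts loudly rather than silently dropping records.
    """
    base = Path(base_dir) if base_dir is not None else None
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if base is not None and not p.is_absolute():
            p = base / p
        if not os.path.exists(p):
            raise FileNotFoundError(f"manifest references missing spectrum file: {p}")
        yield read_xy(p, platform_id=row["platform"], sample_id=row["sample_id"],
                      replicate_index=int(row["replicate"]))
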