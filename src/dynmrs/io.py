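"""Domain types and readers/writers for dynamic MRS data.

Canonical on-disk dialect: a JSON header holding the acquisition grid next
to a TSV matrix of complex samples (``re_<i>``/``im_<i>`` column pairs, one
row per transient).  A minimal NIfTI-MRS reader is provided for
convenience; only singleton spatial dimensions are supported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionGrid",
    "FIDSeries",
    "BasisSet",
    "TimeVariable",
    "ResultsTable",
    "FormatError",
    "read_fid_series",
    "write_fid_series",
    "read_basis",
    "write_basis",
    "read_time_variable",
    "write_time_variable",
]


class FormatError(ValueError):
    """Raised when an input file is structurally invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionGrid:
    """Sampling grid of a series of FIDs.

    Parameters
    ----------
    dwell_time
        Seconds per FID sample.
    n_points
        Samples per FID.
    spectrometer_freq
        Spectrometer frequency in MHz.
    ppm_reference
        Chemical shift (ppm) mapped to zero frequency offset (the centre
        bin of the spectrum).
    """

    dwell_time: float
    n_points: int
    spectrometer_freq: float
    ppm_reference: float = 4.65

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be > 0")

    @property
    def bandwidth(self) -> float:
        """Spectral bandwidth in Hz (= 1 / dwell_time)."""
        return 1.0 / self.dwell_time

    @property
    def tau(self) -> np.ndarray:
        """FID time axis in seconds (index * dwell_time)."""
        return np.arange(self.n_points) * self.dwell_time

    @property
    def nu_hz(self) -> np.ndarray:
        """Ascending frequency-offset axis (Hz), zero at the centre bin."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_time))

    @property
    def ppm(self) -> np.ndarray:
        """Ascending chemical-shift axis; affine in the frequency axis."""
        return self.ppm_reference + self.nu_hz / self.spectrometer_freq

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(ppm) - self.ppm_reference) * self.spectrometer_freq

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(hz) / self.spectrometer_freq + self.ppm_reference

    def fid_to_spec(self, fid: np.ndarray) -> np.ndarray:
        """Unitary DFT of a FID (last axis), centred on the ascending axis."""
        return np.fft.fftshift(np.fft.fft(fid, axis=-1, norm="ortho"), axes=-1)

    def spec_to_fid(self, spec: np.ndarray) -> np.ndarray:
        return np.fft.ifft(np.fft.ifftshift(spec, axes=-1), axis=-1, norm="ortho")

    def ppm_window_mask(self, ppm_range: tuple[float, float] | None) -> np.ndarray:
        """Boolean mask over spectral bins for a (low, high) ppm window."""
        if ppm_range is None:
            return np.ones(self.n_points, dtype=bool)
        low, high = ppm_range
        if not low < high:
            raise ValueError("ppm window must satisfy low < high")
        ax = self.ppm
        return (ax >= low) & (ax <= high)

    def to_dict(self) -> dict:
        return {
            "dwell_time": self.dwell_time,
            "n_points": self.n_points,
            "spectrometer_freq": self.spectrometer_freq,
            "ppm_reference": self.ppm_reference,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionGrid":
        missing = {"dwell_time", "n_points", "spectrometer_freq"} - set(d)
        if missing:
            raise FormatError(f"grid header missing fields: {sorted(missing)}")
        return cls(
            dwell_time=float(d["dwell_time"]),
            n_points=int(d["n_points"]),
            spectrometer_freq=float(d["spectrometer_freq"]),
            ppm_reference=float(d.get("ppm_reference", 4.65)),
        )


@dataclass
class FIDSeries:
    """Ordered complex transients sharing one acquisition grid."""

    grid: AcquisitionGrid
    transients: np.ndarray  # (T, n_points) complex
    transient_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.transients = np.atleast_2d(np.asarray(self.transients, dtype=complex))
        if self.transients.shape[0] < 1:
            raise ValueError("need at least one transient")
        if self.transients.shape[1] != self.grid.n_points:
            raise FormatError(
                f"transient length {self.transients.shape[1]} != grid n_points "
                f"{self.grid.n_points}"
            )
        if self.transient_labels is not None and len(self.transient_labels) != self.n_transients:
            raise ValueError("transient_labels length mismatch")

    @property
    def n_transients(self) -> int:
        return self.transients.shape[0]

    def spectra(self) -> np.ndarray:
        """(T, n_points) complex spectra on the ascending frequency axis."""
        return self.grid.fid_to_spec(self.transients)


@dataclass
class BasisSet:
    """Named complex basis FIDs with metabolite-group assignments.

    ``groups`` maps each metabolite name to an integer group id; metabolites
    in the same group share line-broadening and frequency-shift parameters
    during fitting.  ``per_timepoint`` optionally supplies a distinct basis
    per dynamic condition (e.g. editing ON/OFF), all with identical names.
    """

    names: list[str]
    fids: np.ndarray  # (K, n_points) complex
    grid: AcquisitionGrid
    groups: dict[str, int] = field(default_factory=dict)
    per_timepoint: list["BasisSet"] | None = None

    def __post_init__(self) -> None:
        self.fids = np.atleast_2d(np.asarray(self.fids, dtype=complex))
        if len(self.names) != self.fids.shape[0]:
            raise ValueError("names/fids length mismatch")
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate basis names")
        if self.fids.shape[1] != self.grid.n_points:
            raise FormatError("basis FID length != grid n_points")
        if not self.groups:
            self.groups = {n: i for i, n in enumerate(self.names)}
        missing = set(self.names) - set(self.groups)
        if missing:
            raise ValueError(f"metabolites without a group: {sorted(missing)}")
        if self.per_timepoint is not None:
            for b in self.per_timepoint:
                if b.names != self.names:
                    raise FormatError("per-timepoint bases must share names")

    @property
    def n_metabolites(self) -> int:
        return len(self.names)

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    @property
    def group_index(self) -> np.ndarray:
        """(K,) array mapping metabolite k to its group position 0..G-1."""
        gids = sorted(set(self.groups.values()))
        pos = {g: i for i, g in enumerate(gids)}
        return np.array([pos[self.groups[n]] for n in self.names])

    def basis_for_timepoint(self, t: int, n_timepoints: int | None = None) -> "BasisSet":
        if self.per_timepoint is None:
            return self
        return self.per_timepoint[t % len(self.per_timepoint)]

    def with_groups(self, groups: dict[str, int]) -> "BasisSet":
        return BasisSet(self.names, self.fids, self.grid, dict(groups), self.per_timepoint)

    def subset(self, names: Sequence[str]) -> "BasisSet":
        idx = [self.names.index(n) for n in names]
        per = None
        if self.per_timepoint is not None:
            per = [b.subset(names) for b in self.per_timepoint]
        return BasisSet(
            list(names),
            self.fids[idx],
            self.grid,
            {n: self.groups[n] for n in names},
            per,
        )


@dataclass
class TimeVariable:
    """Per-transient experimental covariates (design rows, b/g, ...)."""

    columns: dict[str, np.ndarray]
    kind: str = "custom"

    _BVEC_COLS = ("b", "gx", "gy", "gz")

    def __post_init__(self) -> None:
        lengths = {k: len(np.atleast_1d(v)) for k, v in self.columns.items()}
        if len(set(lengths.values())) > 1:
            raise FormatError(f"time-variable columns differ in length: {lengths}")
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        if self.kind == "bval_bvec":
            self._validate_bvecs()

    def _validate_bvecs(self) -> None:
        b = self.columns["b"]
        if np.any(b < 0):
            raise ValueError("b-values must be >= 0")
        g = np.stack([self.columns[c] for c in ("gx", "gy", "gz")], axis=1)
        norms = np.linalg.norm(g, axis=1)
        weighted = b > 0
        bad = weighted & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            warnings.warn("non-unit gradient directions at b > 0; renormalizing")
            g[bad] /= norms[bad, None]
            for i, c in enumerate(("gx", "gy", "gz")):
                self.columns[c] = g[:, i]

    @property
    def n_transients(self) -> int:
        return len(next(iter(self.columns.values())))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    @property
    def column_names(self) -> list[str]:
        return list(self.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str | None = None) -> "TimeVariable":
        cols = {str(c): df[c].to_numpy(dtype=float) for c in df.columns}
        if kind is None:
            kind = "bval_bvec" if set(cls._BVEC_COLS) <= set(cols) else "design_matrix"
        return cls(cols, kind=kind)


@dataclass
class ResultsTable:
    """Output of a fit: free-parameter estimates with uncertainty.

    ``mapped_params`` holds the per-transient spectral parameters implied by
    the free parameters (one entry per transient).
    """

    param_names: list[str]
    free_params: np.ndarray  # (P,)
    covariance: np.ndarray  # (P, P)
    aic: float
    mapped_params: list | None = None
    init_record: dict = field(default_factory=dict)
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.free_params = np.asarray(self.free_params, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        P = len(self.param_names)
        if self.free_params.shape != (P,) or self.covariance.shape != (P, P):
            raise ValueError("parameter/covariance dimension mismatch")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8, rtol=1e-6):
            raise ValueError("covariance must be symmetric")

    @property
    def uncertainties(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def __getitem__(self, name: str) -> float:
        return float(self.free_params[self.param_names.index(name)])

    def sd(self, name: str) -> float:
        return float(self.uncertainties[self.param_names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.free_params,
                "sd": self.uncertainties,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FID series I/O
# ---------------------------------------------------------------------------


def _series_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in {".json", ".tsv"}:
        p = p.with_suffix("")
    return p.with_suffix(".json"), p.with_suffix(".tsv")


def write_fid_series(series: FIDSeries, path: str | Path) -> None:
    """Write a FID series as a JSON grid header plus a TSV complex matrix."""
    hdr_path, tsv_path = _series_paths(path)
    header = {"grid": series.grid.to_dict()}
    if series.transient_labels is not None:
        header["transient_labels"] = list(series.transient_labels)
    hdr_path.write_text(json.dumps(header, indent=1))
    n = series.grid.n_points
    data = {}
    for i in range(n):
        data[f"re_{i}"] = series.transients[:, i].real
        data[f"im_{i}"] = series.transients[:, i].imag
    pd.DataFrame(data).to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")


def read_fid_series(path: str | Path, spectrometer_freq: float | None = None) -> FIDSeries:
    """Read a FID series from the JSON+TSV dialect or a minimal NIfTI-MRS file."""
    p = Path(path)
    if p.suffix in {".nii", ".gz"} or p.name.endswith(".nii.gz"):
        return _read_nifti_mrs(p, spectrometer_freq=spectrometer_freq)
    hdr_path, tsv_path = _series_paths(p)
    if not hdr_path.exists():
        raise FormatError(f"missing header file {hdr_path}")
    header = json.loads(hdr_path.read_text())
    if "grid" not in header:
        raise FormatError("header missing 'grid' object")
    grid = AcquisitionGrid.from_dict(header["grid"])
    df = pd.read_csv(tsv_path, sep="\t")
    expected = [f"{part}_{i}" for i in range(grid.n_points) for part in ("re", "im")]
    if set(expected) - set(df.columns):
        raise FormatError("transient matrix columns do not match grid n_points")
    re = df[[f"re_{i}" for i in range(grid.n_points)]].to_numpy()
    im = df[[f"im_{i}" for i in range(grid.n_points)]].to_numpy()
    return FIDSeries(grid, re + 1j * im, header.get("transient_labels"))


def _read_nifti_mrs(path: Path, spectrometer_freq: float | None = None) -> FIDSeries:
    import nibabel as nib

    img = nib.load(str(path))
    shape = img.shape
    if len(shape) < 4 or any(s != 1 for s in shape[:3]):
        raise FormatError("only singleton spatial dimensions are supported")
    data = np.asarray(img.dataobj)
    fids = data.reshape(shape[3], -1, order="F").T  # (T, n_points)
    dwell = float(img.header["pixdim"][4])
    freq = spectrometer_freq
    ppm_ref = 4.65
    for ext in img.header.extensions:
        try:
            meta = json.loads(ext.get_content())
        except Exception:  # pragma: no cover - non-JSON extension
            continue
        if "SpectrometerFrequency" in meta:
            f = meta["SpectrometerFrequency"]
            freq = float(f[0] if isinstance(f, (list, tuple)) else f)
        ppm_ref = float(meta.get("PpmReference", ppm_ref))
    if freq is None:
        raise FormatError("spectrometer frequency not found in NIfTI-MRS header")
    grid = AcquisitionGrid(dwell, shape[3], freq, ppm_ref)
    return FIDSeries(grid, fids.astype(complex))


# ---------------------------------------------------------------------------
# Basis I/O
# ---------------------------------------------------------------------------


def _basis_entry_to_dict(name: str, fid: np.ndarray, grid: AcquisitionGrid, group: int) -> dict:
    return {
        "name": name,
        "group": group,
        "grid": grid.to_dict(),
        "fid_re": fid.real.tolist(),
        "fid_im": fid.imag.tolist(),
    }


def write_basis(basis: BasisSet, path: str | Path) -> None:
    """Write a basis set as one JSON file per metabolite in a directory.

    A basis with per-timepoint variants writes one subdirectory per
    condition (``cond_0``, ``cond_1``, ...).
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    if basis.per_timepoint is not None:
        for t, sub in enumerate(basis.per_timepoint):
            write_basis(sub, root / f"cond_{t}")
        return
    for name, fid in zip(basis.names, basis.fids):
        entry = _basis_entry_to_dict(name, fid, basis.grid, basis.groups[name])
        (root / f"{name}.json").write_text(json.dumps(entry))


def _read_flat_basis(root: Path) -> BasisSet:
    files = sorted(root.glob("*.json"))
    if not files:
        raise FormatError(f"no basis JSON files in {root}")
    names, fids, groups = [], [], {}
    grid = None
    for f in files:
        entry = json.loads(f.read_text())
        g = AcquisitionGrid.from_dict(entry["grid"])
        if grid is None:
            grid = g
        elif g != grid:
            raise FormatError(f"basis entry {f.name} has incompatible grid")
        name = entry["name"]
        if name in groups:
            raise FormatError(f"duplicate basis name {name!r}")
        names.append(name)
        fids.append(np.asarray(entry["fid_re"]) + 1j * np.asarray(entry["fid_im"]))
        groups[name] = int(entry.get("group", len(names) - 1))
    return BasisSet(names, np.array(fids), grid, groups)


def read_basis(path: str | Path) -> BasisSet:
    """Read a basis directory (or single-entry JSON file).

    Subdirectories, when present, are treated as per-condition bases
    (sorted by directory name) and populate ``per_timepoint``.
    """
    root = Path(path)
    if root.is_file():
        entry = json.loads(root.read_text())
        grid = AcquisitionGrid.from_dict(entry["grid"])
        fid = np.asarray(entry["fid_re"]) + 1j * np.asarray(entry["fid_im"])
        return BasisSet([entry["name"]], fid[None, :], grid)
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    if subdirs:
        per = [_read_flat_basis(d) for d in subdirs]
        base = per[0]
        for b in per[1:]:
            if b.names != base.names:
                raise FormatError("per-condition bases must share metabolite names")
        return BasisSet(base.names, base.fids, base.grid, dict(base.groups), per)
    return _read_flat_basis(root)


# ---------------------------------------------------------------------------
# Time-variable I/O
# ---------------------------------------------------------------------------


def write_time_variable(tvar: TimeVariable, path: str | Path) -> None:
    tvar.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_time_variable(
    path: str | Path, kind: str | None = None, n_transients: int | None = None
) -> TimeVariable:
    df = pd.read_csv(path, sep="\t")
    tvar = TimeVariable.from_frame(df, kind=kind)
    if n_transients is not None and tvar.n_transients != n_transients:
        raise FormatError(
            f"time variable has {tvar.n_transients} rows, expected {n_transients}"
        )
    return tvar
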