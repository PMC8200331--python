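"""Montage and recording data model, plus SNIRF / TSV container I/O.

The montage is the coordinate frame for everything downstream: a channel is a
source-detector optode pair with an inter-optode distance in mm, and channel
order is fixed at load time and shared by every array in the pipeline
(intensity, optical density, hemoglobin, connectomes, ICA maps).

Two on-disk forms are supported:

* SNIRF (the HDF5-based fNIRS standard), the canonical container.  Only the
  continuous-wave subset is written/read: ``/nirs/data1`` with a
  ``measurementList``, ``/nirs/probe/wavelengths`` and 2-D optode positions.
  Because SNIRF carries optode *positions* rather than distances, the montage
  table (label, source, detector, distance_mm) is additionally stored verbatim
  as a TSV string under ``/nirs/metaDataTags/channelTable`` and is preferred on
  load; files without the tag fall back to distances computed from positions.
* A plain-text dialect for fixtures: an intensity TSV (one column per
  channel x wavelength) next to a montage TSV with documented column order
  ``label, source, detector, distance_mm``.

Wavelength order is normalised to (760, 850) nm on load regardless of file
order.  Channel labels are user-facing and 1-based ("Ch 1", ...); internal
indexing is 0-based.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import DataError, FormatError

WAVELENGTHS_NM = (760.0, 850.0)

MONTAGE_COLUMNS = ["label", "source", "detector", "distance_mm"]


@dataclass(frozen=True)
class Montage:
    """Channel geometry: source-detector pairing, distance and label.

    Parameters
    ----------
    labels : tuple of str
        Unique channel labels, user-facing ("Ch 1", ...).
    source_ids, detector_ids : tuple of int
        1-based optode identifiers.
    distances_mm : tuple of float
        Inter-optode distance per channel, strictly positive.
    """

    labels: tuple
    source_ids: tuple
    detector_ids: tuple
    distances_mm: tuple

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def channels(self):
        """Rows as (label, source_id, detector_id, distance_mm) tuples."""
        return list(
            zip(self.labels, self.source_ids, self.detector_ids, self.distances_mm)
        )

    def validate(self):
        """Return a list of human-readable invariant violations (empty iff valid)."""
        violations = []
        n = len(self.labels)
        if n == 0:
            violations.append("montage has no channels")
        for name, seq in (
            ("source_ids", self.source_ids),
            ("detector_ids", self.detector_ids),
            ("distances_mm", self.distances_mm),
        ):
            if len(seq) != n:
                violations.append(f"{name} has {len(seq)} entries for {n} labels")
        seen = set()
        for lab in self.labels:
            if lab in seen:
                violations.append(f"duplicate channel label {lab!r}")
            seen.add(lab)
        for lab, s, d, dist in zip(
            self.labels, self.source_ids, self.detector_ids, self.distances_mm
        ):
            if not (isinstance(s, (int, np.integer)) and s > 0):
                violations.append(f"channel {lab!r}: source id {s!r} not a positive integer")
            if not (isinstance(d, (int, np.integer)) and d > 0):
                violations.append(f"channel {lab!r}: detector id {d!r} not a positive integer")
            if not dist > 0:
                violations.append(f"channel {lab!r}: distance_mm {dist} not > 0")
        return violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "source": self.source_ids,
                "detector": self.detector_ids,
                "distance_mm": self.distances_mm,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Montage":
        missing = [c for c in MONTAGE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"montage table missing columns {missing}")
        return cls(
            labels=tuple(str(x) for x in df["label"]),
            source_ids=tuple(int(x) for x in df["source"]),
            detector_ids=tuple(int(x) for x in df["detector"]),
            distances_mm=tuple(float(x) for x in df["distance_mm"]),
        )


def validate_montage(montage: Montage):
    """Report invariant violations of a montage; empty list iff valid."""
    return montage.validate()


def make_montage(n_channels: int, distances_mm=None, seed: int = 0) -> Montage:
    """Construct a synthetic but well-formed montage with ``n_channels`` channels.

    Source/detector ids enumerate distinct pairs; distances default to values
    drawn reproducibly from the 20-45 mm range typical of whole-head infant
    probes, mirrored between hemisphere halves (channel i and i + n/2 share a
    distance when n is even).
    """
    if n_channels <= 0:
        raise DataError("n_channels must be positive")
    n_sources = max(2, int(np.ceil(np.sqrt(n_channels * 14 / 19))))
    n_detectors = max(2, int(np.ceil(n_channels / n_sources)) + 1)
    pairs = [(s, d) for s in range(1, n_sources + 1) for d in range(1, n_detectors + 1)]
    pairs = pairs[:n_channels]
    if distances_mm is None:
        rng = np.random.default_rng(seed)
        half = n_channels // 2
        base = np.round(rng.uniform(20.0, 45.0, size=n_channels - half), 1)
        if 2 * half == n_channels:
            distances_mm = np.concatenate([base, base])
        else:
            extra = np.round(rng.uniform(20.0, 45.0, size=n_channels - base.size), 1)
            distances_mm = np.concatenate([base, extra])[:n_channels]
    distances_mm = np.asarray(distances_mm, float)
    return Montage(
        labels=tuple(f"Ch {i + 1}" for i in range(n_channels)),
        source_ids=tuple(p[0] for p in pairs),
        detector_ids=tuple(p[1] for p in pairs),
        distances_mm=tuple(distances_mm),
    )


@dataclass
class RawRecording:
    """Raw dual-wavelength light-intensity recording.

    ``intensity`` has shape (2 wavelengths, channels, time) with the wavelength
    axis ordered (760, 850) nm.  Intensities must be strictly positive wherever
    valid, since optical density takes their logarithm.
    """

    intensity: np.ndarray
    fs_hz: float
    montage: Montage
    wavelengths_nm: tuple = WAVELENGTHS_NM
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    def validate(self):
        if self.fs_hz <= 0:
            raise DataError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.intensity.ndim != 3 or self.intensity.shape[0] != 2:
            raise FormatError(
                f"intensity must be (2, channels, time), got {self.intensity.shape}"
            )
        if self.intensity.shape[1] != self.montage.n_channels:
            raise FormatError(
                f"intensity has {self.intensity.shape[1]} channels, montage "
                f"{self.montage.n_channels}"
            )
        bad = ~(np.isfinite(self.intensity) & (self.intensity > 0))
        if bad.any():
            w, c, t = (int(i) for i in np.argwhere(bad)[0])
            raise DataError(
                "non-positive or non-finite intensity at wavelength "
                f"{self.wavelengths_nm[w]:g} nm, channel {self.montage.labels[c]!r} "
                f"(index {c}), sample {t}"
            )
        violations = self.montage.validate()
        if violations:
            raise DataError("invalid montage: " + "; ".join(violations))


@dataclass
class HbSeries:
    """Per-subject chromophore time series.

    ``hbo`` and ``hbr`` are (channels, time) concentration changes in
    micromolar (uM), sharing the montage's channel order.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs_hz: float
    montage: Montage
    units: str = "uM"
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def validate(self):
        if self.hbo.shape != self.hbr.shape:
            raise FormatError(
                f"hbo shape {self.hbo.shape} != hbr shape {self.hbr.shape}"
            )
        if self.hbo.shape[0] != self.montage.n_channels:
            raise FormatError("channel count does not match montage")
        if not (np.isfinite(self.hbo).all() and np.isfinite(self.hbr).all()):
            raise DataError("non-finite values in hemoglobin series")

    def stacked(self) -> np.ndarray:
        """Rows 0..C-1 = HbO channels, rows C..2C-1 = HbR channels."""
        return np.vstack([self.hbo, self.hbr])


# ---------------------------------------------------------------------------
# SNIRF I/O
# ---------------------------------------------------------------------------

def _write_str(group, name, value):
    group.create_dataset(name, data=np.bytes_(value))


def save_recording(rec: RawRecording, path, format: str = None, montage_path=None):
    """Write a recording to disk (SNIRF by default, TSV matrix dialect on request).

    ``format`` is inferred from the path suffix when omitted (".snirf" vs
    ".tsv").  For the matrix dialect the montage table is written to
    ``montage_path`` (default: path + ".montage.tsv").
    """
    rec.validate()
    path = str(path)
    if format is None:
        format = "matrix" if path.endswith(".tsv") else "snirf"
    if format == "snirf":
        _save_snirf(rec, path)
    elif format == "matrix":
        _save_matrix(rec, path, montage_path)
    else:
        raise FormatError(f"unknown format {format!r}")
    return path


def _save_snirf(rec: RawRecording, path):
    C = rec.n_channels
    T = rec.n_samples
    # column order: wavelength-major (all channels at 760, then all at 850)
    data = np.empty((T, 2 * C))
    for w in range(2):
        data[:, w * C:(w + 1) * C] = rec.intensity[w].T
    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        tags = nirs.create_group("metaDataTags")
        _write_str(tags, "SubjectID", rec.meta.get("subject_id", "synthetic"))
        _write_str(tags, "MeasurementDate", "unknown")
        _write_str(tags, "MeasurementTime", "unknown")
        _write_str(tags, "LengthUnit", "mm")
        _write_str(tags, "TimeUnit", "s")
        _write_str(tags, "FrequencyUnit", "Hz")
        buf = io.StringIO()
        rec.montage.to_frame().to_csv(buf, sep="\t", index=False)
        _write_str(tags, "channelTable", buf.getvalue())
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        n_src = max(rec.montage.source_ids)
        n_det = max(rec.montage.detector_ids)
        # synthetic planar positions; true geometry is not modelled
        probe.create_dataset(
            "sourcePos2D",
            data=np.column_stack([np.arange(n_src, dtype=float) * 30.0, np.zeros(n_src)]),
        )
        probe.create_dataset(
            "detectorPos2D",
            data=np.column_stack(
                [np.arange(n_det, dtype=float) * 30.0, np.full(n_det, 30.0)]
            ),
        )
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.array([0.0, 1.0 / rec.fs_hz]))
        for w in range(2):
            for c in range(C):
                ml = d1.create_group(f"measurementList{w * C + c + 1}")
                ml.create_dataset("sourceIndex", data=rec.montage.source_ids[c])
                ml.create_dataset("detectorIndex", data=rec.montage.detector_ids[c])
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)


def _read_scalar(ds):
    v = ds[()]
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.ndarray) and v.size == 1:
        return v.reshape(-1)[0]
    return v


def _load_snirf(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f.get("nirs") or f.get("nirs1")
        if nirs is None:
            raise FormatError(f"{path}: no /nirs group")
        d1 = nirs.get("data1")
        if d1 is None:
            raise FormatError(f"{path}: no /nirs/data1 group")
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"]).reshape(-1)
        if time.size == 2:
            fs = 1.0 / float(time[1] - time[0]) if time[0] == 0 else 1.0 / float(time[1])
        else:
            fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = np.asarray(nirs["probe"]["wavelengths"]).reshape(-1)
        ml_names = sorted(
            (k for k in d1.keys() if k.startswith("measurementList")),
            key=lambda k: int(re.sub(r"\D", "", k)),
        )
        if len(ml_names) != data.shape[1]:
            raise FormatError(
                f"{path}: {len(ml_names)} measurementList entries for "
                f"{data.shape[1]} data columns"
            )
        cols = []
        for k in ml_names:
            ml = d1[k]
            cols.append(
                (
                    int(_read_scalar(ml["sourceIndex"])),
                    int(_read_scalar(ml["detectorIndex"])),
                    int(_read_scalar(ml["wavelengthIndex"])),
                )
            )
        tags = nirs.get("metaDataTags", {})
        table = None
        if "channelTable" in tags:
            table = pd.read_csv(io.StringIO(_read_scalar(tags["channelTable"])), sep="\t")
        src_pos = np.asarray(nirs["probe"].get("sourcePos2D", np.zeros((0, 2))))
        det_pos = np.asarray(nirs["probe"].get("detectorPos2D", np.zeros((0, 2))))

    # map requested wavelength order onto file order
    order = []
    for target in WAVELENGTHS_NM:
        idx = int(np.argmin(np.abs(wavelengths - target)))
        order.append(idx + 1)  # wavelengthIndex is 1-based
    if order[0] == order[1]:
        raise FormatError(f"{path}: needs two distinct wavelength planes, got {wavelengths}")

    # channel identity = (source, detector) in first-plane column order
    chan_pairs = [(s, d) for s, d, w in cols if w == order[0]]
    if not chan_pairs:
        raise FormatError(f"{path}: missing wavelength plane for {WAVELENGTHS_NM[0]} nm")
    col_of = {(s, d, w): i for i, (s, d, w) in enumerate(cols)}
    C = len(chan_pairs)
    T = data.shape[0]
    intensity = np.empty((2, C, T))
    for w_i, w_idx in enumerate(order):
        for c, (s, d) in enumerate(chan_pairs):
            key = (s, d, w_idx)
            if key not in col_of:
                raise FormatError(
                    f"{path}: missing wavelength plane "
                    f"{WAVELENGTHS_NM[w_i]:g} nm for channel S{s}-D{d}"
                )
            intensity[w_i, c] = data[:, col_of[key]]

    if table is not None:
        montage = Montage.from_frame(table)
    else:
        dists = []
        for s, d in chan_pairs:
            if s <= len(src_pos) and d <= len(det_pos):
                dists.append(float(np.linalg.norm(src_pos[s - 1] - det_pos[d - 1])))
            else:
                dists.append(30.0)
        montage = Montage(
            labels=tuple(f"S{s}-D{d}" for s, d in chan_pairs),
            source_ids=tuple(s for s, d in chan_pairs),
            detector_ids=tuple(d for s, d in chan_pairs),
            distances_mm=tuple(dists),
        )
    rec = RawRecording(intensity=intensity, fs_hz=fs, montage=montage)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# plain-matrix (TSV) dialect
# ---------------------------------------------------------------------------

def _save_matrix(rec: RawRecording, path, montage_path=None):
    C = rec.n_channels
    cols = {}
    for w, wl in enumerate(rec.wavelengths_nm):
        for c, lab in enumerate(rec.montage.labels):
            cols[f"{lab}|{wl:g}nm"] = rec.intensity[w, c]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs_hz!r}\n")
        fh.write(f"# wavelengths_nm={rec.wavelengths_nm[0]:g},{rec.wavelengths_nm[1]:g}\n")
        df.to_csv(fh, sep="\t", index=False)
    if montage_path is None:
        montage_path = str(path) + ".montage.tsv"
    rec.montage.to_frame().to_csv(montage_path, sep="\t", index=False)


def _load_matrix(path, montage_path=None) -> RawRecording:
    if montage_path is None:
        montage_path = str(path) + ".montage.tsv"
    montage = Montage.from_frame(pd.read_csv(montage_path, sep="\t"))
    fs = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# fs_hz="):
                fs = float(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    if fs is None:
        raise FormatError(f"{path}: missing '# fs_hz=' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    C = montage.n_channels
    T = len(df)
    intensity = np.empty((2, C, T))
    for w, wl in enumerate(WAVELENGTHS_NM):
        for c, lab in enumerate(montage.labels):
            col = f"{lab}|{wl:g}nm"
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r} (wavelength plane)")
            intensity[w, c] = df[col].to_numpy()
    rec = RawRecording(intensity=intensity, fs_hz=fs, montage=montage)
    rec.validate()
    return rec


def load_recording(path, format: str = None, montage_path=None) -> RawRecording:
    """Load a recording from SNIRF or the TSV matrix dialect.

    The returned recording has wavelength planes ordered (760, 850) nm and a
    validated montage; channel order matches the montage order.
    """
    path = str(path)
    if format is None:
        format = "matrix" if path.endswith(".tsv") else "snirf"
    if format == "snirf":
        return _load_snirf(path)
    if format == "matrix":
        return _load_matrix(path, montage_path)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# HbSeries containers (pipeline intermediates)
# ---------------------------------------------------------------------------

def save_hb(hb: HbSeries, path):
    """Persist an HbSeries (.npz fast path, .tsv plain-text path)."""
    hb.validate()
    path = str(path)
    if path.endswith(".npz"):
        np.savez_compressed(
            path,
            hbo=hb.hbo,
            hbr=hb.hbr,
            fs_hz=hb.fs_hz,
            units=np.bytes_(hb.units),
            labels=np.array(hb.montage.labels),
            source_ids=np.array(hb.montage.source_ids),
            detector_ids=np.array(hb.montage.detector_ids),
            distances_mm=np.array(hb.montage.distances_mm),
        )
    elif path.endswith(".tsv"):
        cols = {}
        for c, lab in enumerate(hb.montage.labels):
            cols[f"{lab}|HbO"] = hb.hbo[c]
            cols[f"{lab}|HbR"] = hb.hbr[c]
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={hb.fs_hz!r}\n")
            fh.write(f"# units={hb.units}\n")
            pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)
        hb.montage.to_frame().to_csv(path + ".montage.tsv", sep="\t", index=False)
    else:
        raise FormatError(f"unsupported HbSeries container suffix for {path!r}")
    return path


def load_hb(path) -> HbSeries:
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path) as z:
            montage = Montage(
                labels=tuple(str(x) for x in z["labels"]),
                source_ids=tuple(int(x) for x in z["source_ids"]),
                detector_ids=tuple(int(x) for x in z["detector_ids"]),
                distances_mm=tuple(float(x) for x in z["distances_mm"]),
            )
            hb = HbSeries(
                hbo=z["hbo"],
                hbr=z["hbr"],
                fs_hz=float(z["fs_hz"]),
                montage=montage,
                units=bytes(z["units"].item()).decode()
                if z["units"].dtype.kind == "S"
                else str(z["units"]),
            )
    elif path.endswith(".tsv"):
        montage = Montage.from_frame(pd.read_csv(path + ".montage.tsv", sep="\t"))
        fs = units = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("# fs_hz="):
                    fs = float(line.split("=", 1)[1])
                elif line.startswith("# units="):
                    units = line.split("=", 1)[1].strip()
                if not line.startswith("#"):
                    break
        df = pd.read_csv(path, sep="\t", comment="#")
        hbo = np.vstack([df[f"{lab}|HbO"].to_numpy() for lab in montage.labels])
        hbr = np.vstack([df[f"{lab}|HbR"].to_numpy() for lab in montage.labels])
        hb = HbSeries(hbo=hbo, hbr=hbr, fs_hz=fs, montage=montage, units=units or "uM")
    else:
        raise FormatError(f"unsupported HbSeries container suffix for {path!r}")
    hb.validate()
    return hb
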