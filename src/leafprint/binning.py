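"""Spectral binning of flow-infusion ESI-MS fingerprints.

Flow-infusion electrospray ionisation mass spectrometry (FIE-MS) acquires a
few minutes of scans per sample with no chromatographic separation.  Each
centroided scan is a list of (m/z, intensity) peaks; the fingerprint of a
sample is obtained by summing centroid intensities into fixed-width m/z bins
(one feature per bin per ionisation mode) and averaging bin values across the
scans of the infusion peak.  This module holds the core data containers
(:class:`ScanSet`, :class:`FeatureMatrix`) and the binning / filtering /
normalisation chain that turns raw scans into a log2 feature matrix:

    read_mzml -> select_infusion_scans -> bin_scans
        -> occupancy_filter -> qc_rsd_filter -> normalise_tic -> log2_transform

Bins are half-open intervals ``[k*w, (k+1)*w)`` of width ``w`` (default
0.01 m/z) and are named ``<mode><lower edge at bin precision>`` with mode
``p`` (positive) or ``n`` (negative), e.g. ``n341.11``.  Alongside the
integer grid each bin carries an *accurate* m/z — the intensity-weighted mean
of the centroids that fell into it — which downstream accurate-mass
annotation uses in place of the coarse bin label.
"""

from __future__ import annotations

import base64
import logging
import math
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("leafprint")

#: default acquisition window (m/z) and bin width
MZ_RANGE: tuple[float, float] = (55.0, 1200.0)
BIN_WIDTH: float = 0.01

#: processing stages, in the only order transitions may occur
STAGES = ("raw", "occupancy_filtered", "qc_filtered", "normalised", "log2")

POSITIVE, NEGATIVE = "positive", "negative"
_MODE_PREFIX = {POSITIVE: "p", NEGATIVE: "n"}
_PREFIX_MODE = {v: k for k, v in _MODE_PREFIX.items()}


class StageError(ValueError):
    """Raised when an operation is applied at the wrong processing stage."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Scan:
    """One centroided scan: sorted m/z and non-negative intensity arrays."""

    mode: str
    index: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mode not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown ionisation mode {self.mode!r}")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative centroid intensity")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz, self.intensity = self.mz[order], self.intensity[order]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class ScanSet:
    """All scans of one sample, both ionisation modes."""

    sample_id: str
    scans: list[Scan] = field(default_factory=list)

    def by_mode(self, mode: str) -> list[Scan]:
        return [s for s in self.scans if s.mode == mode]

    @property
    def modes(self) -> list[str]:
        seen = []
        for s in self.scans:
            if s.mode not in seen:
                seen.append(s.mode)
        return seen

    @property
    def scan_indices(self) -> list[int]:
        return sorted({s.index for s in self.scans})


@dataclass
class FeatureMatrix:
    """Samples x m/z-bin intensity matrix with a processing-stage flag.

    ``data`` is indexed by sample id with bin-id columns; ``bin_info`` is
    indexed by bin id with columns ``mode`` and ``mz`` (accurate m/z).
    """

    data: pd.DataFrame
    bin_info: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if list(self.data.columns) != list(self.bin_info.index):
            self.bin_info = self.bin_info.reindex(self.data.columns)
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate bin ids")
        if self.stage != "log2" and (self.data.to_numpy() < 0).any():
            raise ValueError("negative intensities in a pre-log2 matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_bins(self, bins: list[str], stage: str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(self.data[bins], self.bin_info.loc[bins],
                             stage or self.stage)

    # -- persistence --------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Write data to ``path`` and bin metadata to ``<path>.features.csv``."""
        path = Path(path)
        out = self.data.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False, float_format="%.10g")
        info = self.bin_info.copy()
        info.insert(0, "bin_id", info.index)
        info["stage"] = self.stage
        info.to_csv(path.with_suffix(path.suffix + ".features.csv"),
                    index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        data = pd.read_csv(path).set_index("sample_id")
        data.index = data.index.astype(str)
        data.index.name = None
        side = path.with_suffix(path.suffix + ".features.csv")
        if side.exists():
            info = pd.read_csv(side).set_index("bin_id")
            info.index.name = None
            stage = str(info.pop("stage").iloc[0]) if "stage" in info else "raw"
        else:  # bare matrix: reconstruct mode/centre from the column names
            info = pd.DataFrame({"mode": [_PREFIX_MODE.get(c[0], POSITIVE) for c in data.columns],
                                 "mz": [float(c[1:]) + BIN_WIDTH / 2 for c in data.columns]},
                                index=data.columns)
            stage = "raw"
        return cls(data, info, stage)


def _require_stage(matrix: FeatureMatrix, allowed: tuple[str, ...], op: str) -> None:
    if matrix.stage not in allowed:
        raise StageError(f"{op} expects stage in {allowed}, got {matrix.stage!r}")


# ---------------------------------------------------------------------------
# bin grid helpers
# ---------------------------------------------------------------------------

def bin_decimals(bin_width: float) -> int:
    return max(0, -int(math.floor(math.log10(bin_width) + 1e-9)))

def bin_index(mz: np.ndarray | float, bin_width: float = BIN_WIDTH) -> np.ndarray:
    """Half-open bin index floor(mz / w); boundary values go to the upper bin."""
    # the 1e-6 nudge keeps values that are exactly on a boundary (up to float
    # representation) in the upper bin, per the half-open convention
    return np.floor(np.asarray(mz, dtype=float) / bin_width + 1e-6).astype(np.int64)

def bin_id(mode: str, k: int | np.ndarray, bin_width: float = BIN_WIDTH) -> str:
    dp = bin_decimals(bin_width)
    return f"{_MODE_PREFIX[mode]}{k * bin_width:.{dp}f}"

def parse_bin_id(bid: str, bin_width: float = BIN_WIDTH) -> tuple[str, float]:
    """Return (mode, bin centre m/z) encoded in a bin id."""
    mode = _PREFIX_MODE[bid[0]]
    return mode, float(bid[1:]) + bin_width / 2


# ---------------------------------------------------------------------------
# mzML I/O
# ---------------------------------------------------------------------------

_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_IT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda) -> np.ndarray:
    accs = {c.get("accession") for c in bda if _strip_ns(c.tag) == "cvParam"}
    text = next((c.text or "" for c in bda if _strip_ns(c.tag) == "binary"), "")
    raw = base64.b64decode(text.strip() or b"")
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), accs


def read_mzml(path: str | Path) -> ScanSet:
    """Read a centroided mzML file into a :class:`ScanSet`.

    A deliberately small reader (stdlib XML + base64/zlib): it understands
    the spectrum-level cvParams for polarity and spectrum type and 32/64-bit,
    optionally zlib-compressed, m/z and intensity arrays — the subset of
    mzML that flow-infusion fingerprinting needs.  Spectra are partitioned
    by ionisation polarity; profile-mode spectra are rejected with
    instructions to centroid first; missing polarity metadata is an error.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    scans: list[Scan] = []
    for _, elem in ET.iterparse(str(path)):
        if _strip_ns(elem.tag) != "spectrum":
            continue
        i = len(scans)
        accs = {c.get("accession") for c in elem if _strip_ns(c.tag) == "cvParam"}
        if _ACC_PROFILE in accs:
            raise ValueError(
                f"{path.name}: spectrum {i} is profile-mode; centroid the "
                "data (e.g. msconvert --filter 'peakPicking') before binning")
        if _ACC_CENTROID not in accs:
            raise ValueError(f"{path.name}: spectrum {i} lacks a spectrum-type cvParam")
        if _ACC_POSITIVE in accs:
            mode = POSITIVE
        elif _ACC_NEGATIVE in accs:
            mode = NEGATIVE
        else:
            raise ValueError(f"{path.name}: spectrum {i} lacks polarity metadata")
        sid = elem.get("id", "")
        if "scan=" in sid:  # preserve the acquisition scan number
            idx = int(sid.split("scan=")[1].split()[0])
        else:
            idx = int(elem.get("index", i))
        mz = intensity = None
        for bda in elem.iter():
            if _strip_ns(bda.tag) != "binaryDataArray":
                continue
            arr, bda_accs = _decode_binary(bda)
            if _ACC_MZ_ARRAY in bda_accs:
                mz = arr
            elif _ACC_IT_ARRAY in bda_accs:
                intensity = arr
        if mz is None or intensity is None:
            raise ValueError(f"{path.name}: spectrum {i} lacks m/z or intensity array")
        scans.append(Scan(mode, idx, mz, intensity))
        elem.clear()
    if not scans:
        logger.warning("%s: no spectra found; returning empty ScanSet", path.name)
    return ScanSet(sample_id=path.stem, scans=scans)


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_MZML_SPECTRUM = """\
      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{it_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{it_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

def write_mzml(scanset: ScanSet, path: str | Path) -> None:
    """Write a ScanSet as a minimal centroided mzML document.

    Only the elements the binning stage needs are emitted (polarity and
    centroid cvParams, 64-bit zlib-compressed m/z / intensity arrays); the
    output is readable by pyteomics and round-trips through
    :func:`read_mzml`.
    """
    path = Path(path)
    parts = []
    ordered = sorted(scanset.scans, key=lambda s: (s.index, s.mode))
    for i, scan in enumerate(ordered):
        pol_acc, pol_name = (("MS:1000130", "positive scan") if scan.mode == POSITIVE
                             else ("MS:1000129", "negative scan"))
        mz_b64 = _encode_array(scan.mz)
        it_b64 = _encode_array(scan.intensity)
        parts.append(_MZML_SPECTRUM.format(
            index=i, scan=scan.index, n=len(scan.mz), pol_acc=pol_acc, pol_name=pol_name,
            mz_len=len(mz_b64), mz_b64=mz_b64, it_len=len(it_b64), it_b64=it_b64))
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id="{scanset.sample_id}">\n'
        f'    <spectrumList count="{len(ordered)}">\n'
        + "".join(parts) +
        '    </spectrumList>\n  </run>\n</mzML>\n')
    path.write_text(doc)


# ---------------------------------------------------------------------------
# infusion window and binning
# ---------------------------------------------------------------------------

def select_infusion_scans(scanset: ScanSet, tic_fraction: float = 0.5) -> tuple[int, int]:
    """Select the infusion-peak scan window.

    Returns the longest contiguous run of scan indices in which every scan's
    total ion count (summed over modes) is at least ``tic_fraction`` times the
    maximum scan TIC.  Ties go to the earliest run.
    """
    if not scanset.scans:
        raise ValueError("empty ScanSet")
    if not (0 < tic_fraction <= 1):
        raise ValueError("tic_fraction must be in (0, 1]")
    indices = scanset.scan_indices
    tic = {i: 0.0 for i in indices}
    for s in scanset.scans:
        tic[s.index] += s.tic
    tics = np.array([tic[i] for i in indices])
    if tics.max() <= 0:
        raise ValueError("all scans have zero TIC; cannot select an infusion window")
    ok = tics >= tic_fraction * tics.max()
    best, cur = None, None
    for pos, flag in enumerate(ok):
        if flag:
            cur = pos if cur is None else cur
            if best is None or pos - cur > best[1] - best[0]:
                best = (cur, pos)
        else:
            cur = None
    lo, hi = best
    return indices[lo], indices[hi]


def bin_scans(scanset: ScanSet,
              window: tuple[int, int] | None = None,
              bin_width: float = BIN_WIDTH,
              mz_range: tuple[float, float] = MZ_RANGE) -> FeatureMatrix:
    """Bin one sample's scans into a single-row :class:`FeatureMatrix`.

    Centroid intensities within ``[mz_range)`` are summed into half-open bins
    per ionisation mode and per scan, then averaged over the scans of
    ``window`` (inclusive; all scans when None).  Centroids outside the range
    are excluded and counted in a log summary.  Each bin's accurate m/z is
    the intensity-weighted mean of its centroids.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if window is None:
        ids = scanset.scan_indices
        window = (min(ids), max(ids)) if ids else (0, 0)
    lo, hi = window
    if lo > hi:
        raise ValueError(f"invalid scan window {window}")

    per_mode_sums: dict[str, dict[int, float]] = {}
    mz_weighted: dict[str, dict[int, float]] = {}
    n_scans = {m: 0 for m in (POSITIVE, NEGATIVE)}
    excluded = 0
    for scan in scanset.scans:
        if not (lo <= scan.index <= hi):
            continue
        n_scans[scan.mode] += 1
        inside = (scan.mz >= mz_range[0]) & (scan.mz < mz_range[1])
        excluded += int((~inside).sum())
        ks = bin_index(scan.mz[inside], bin_width)
        sums = per_mode_sums.setdefault(scan.mode, {})
        wmz = mz_weighted.setdefault(scan.mode, {})
        for k, mz, it in zip(ks, scan.mz[inside], scan.intensity[inside]):
            sums[k] = sums.get(k, 0.0) + it
            wmz[k] = wmz.get(k, 0.0) + it * mz
    if excluded:
        logger.info("%s: %d centroids outside m/z range excluded",
                    scanset.sample_id, excluded)

    cols, vals, modes, mzs = [], [], [], []
    for mode in (POSITIVE, NEGATIVE):
        if mode not in per_mode_sums:
            continue
        for k in sorted(per_mode_sums[mode]):
            total = per_mode_sums[mode][k]
            cols.append(bin_id(mode, k, bin_width))
            vals.append(total / max(n_scans[mode], 1))
            modes.append(mode)
            mzs.append(mz_weighted[mode][k] / total if total > 0
                       else (k + 0.5) * bin_width)
    data = pd.DataFrame([vals], index=[scanset.sample_id], columns=cols)
    info = pd.DataFrame({"mode": modes, "mz": mzs}, index=cols)
    return FeatureMatrix(data, info, stage="raw")


def bin_sample_set(scansets: list[ScanSet],
                   tic_fraction: float = 0.5,
                   bin_width: float = BIN_WIDTH,
                   mz_range: tuple[float, float] = MZ_RANGE) -> FeatureMatrix:
    """Bin many samples and align them on the union of bins (absent -> 0).

    Per-bin accurate m/z is combined across samples by intensity weighting.
    """
    rows, infos = [], []
    for ss in scansets:
        window = select_infusion_scans(ss, tic_fraction)
        fm = bin_scans(ss, window, bin_width, mz_range)
        rows.append(fm.data)
        infos.append(fm.bin_info.assign(weight=fm.data.iloc[0]))
    data = pd.concat(rows).fillna(0.0)
    allinfo = pd.concat(infos)
    weights = allinfo["weight"].clip(lower=0) + 1e-300
    acc = allinfo.assign(wmz=allinfo["mz"] * weights, w=weights)
    grouped = acc.groupby(level=0).agg(mode=("mode", "first"),
                                       wmz=("wmz", "sum"), w=("w", "sum"))
    info = pd.DataFrame({"mode": grouped["mode"],
                         "mz": grouped["wmz"] / grouped["w"]})
    info = info.reindex(data.columns)
    logger.info("binned %d samples into %d bins", len(data), data.shape[1])
    return FeatureMatrix(data, info, stage="raw")


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------

def occupancy_filter(matrix: FeatureMatrix, samples: pd.DataFrame,
                     class_key: str = "group",
                     min_occupancy: float = 2 / 3) -> FeatureMatrix:
    """Keep bins detected in at least ``min_occupancy`` of some class.

    Occupancy of a bin in a class is the fraction of that class's biological
    samples (role == "sample") with non-zero intensity; the bin is retained
    iff its best class reaches the threshold.
    """
    _require_stage(matrix, ("raw", "occupancy_filtered"), "occupancy_filter")
    if class_key not in samples.columns:
        raise ValueError(f"class key {class_key!r} not in sample table")
    bio = samples[samples["role"] == "sample"]
    keep = np.zeros(matrix.data.shape[1], dtype=bool)
    for cls, grp in bio.groupby(class_key, observed=True):
        ids = [s for s in grp["sample_id"] if s in matrix.data.index]
        if not ids:
            raise ValueError(f"class {cls!r} has zero samples in the matrix")
        occ = (matrix.data.loc[ids] > 0).mean(axis=0).to_numpy()
        keep |= occ >= min_occupancy
    kept = [b for b, k in zip(matrix.bin_ids, keep) if k]
    logger.info("occupancy filter: %d -> %d bins", len(keep), len(kept))
    return matrix.subset_bins(kept, stage="occupancy_filtered")


def qc_rsd_filter(matrix: FeatureMatrix, samples: pd.DataFrame,
                  max_rsd: float = 0.5) -> FeatureMatrix:
    """Keep bins whose relative s.d. over pooled-QC injections is <= max_rsd.

    RSD uses the n-1 sample standard deviation.  Bins with zero QC mean
    cannot be assessed and are dropped (logged).
    """
    _require_stage(matrix, ("occupancy_filtered", "qc_filtered"), "qc_rsd_filter")
    qc_ids = [s for s in samples.loc[samples["role"] == "QC", "sample_id"]
              if s in matrix.data.index]
    if len(qc_ids) < 2:
        raise ValueError("qc_rsd_filter needs at least 2 QC samples")
    qc = matrix.data.loc[qc_ids]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    zero_mean = mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    keep = (~zero_mean) & (rsd <= max_rsd)
    if int(zero_mean.sum()):
        logger.info("qc_rsd_filter: %d bins dropped for zero QC mean", int(zero_mean.sum()))
    kept = list(matrix.data.columns[keep])
    logger.info("qc_rsd_filter: %d -> %d bins", matrix.data.shape[1], len(kept))
    return matrix.subset_bins(kept, stage="qc_filtered")


def normalise_tic(matrix: FeatureMatrix) -> FeatureMatrix:
    """Scale each sample so its bin sum equals the median pre-scaling row sum."""
    _require_stage(matrix, ("qc_filtered",), "normalise_tic")
    sums = matrix.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample rows: {list(zero.index)}")
    target = float(sums.median())
    data = matrix.data.mul(target / sums, axis=0)
    return FeatureMatrix(data, matrix.bin_info, stage="normalised")


def log2_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Half-minimum-impute zeros, then take log2 elementwise."""
    _require_stage(matrix, ("normalised",), "log2_transform")
    values = matrix.data.to_numpy(copy=True)
    if (values < 0).any():
        raise ValueError("negative intensity in a normalised matrix")
    nonzero = values[values > 0]
    if nonzero.size:
        values[values == 0] = nonzero.min() / 2
    else:
        raise ValueError("matrix is entirely zero")
    data = pd.DataFrame(np.log2(values), index=matrix.data.index,
                        columns=matrix.data.columns)
    return FeatureMatrix(data, matrix.bin_info, stage="log2")


def preprocess(matrix: FeatureMatrix, samples: pd.DataFrame,
               class_key: str = "group", min_occupancy: float = 2 / 3,
               max_rsd: float = 0.5) -> FeatureMatrix:
    """Full raw -> log2 chain with default parameters."""
    fm = occupancy_filter(matrix, samples, class_key, min_occupancy)
    fm = qc_rsd_filter(fm, samples, max_rsd)
    return log2_transform(normalise_tic(fm))
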