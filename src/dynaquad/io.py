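"""Reading and writing scan tables, mzML, MGF and run configurations.

The native on-disk format is a plain TSV scan table (one row per peak, empty
scans keep a single peakless row) plus a JSON sidecar with run metadata.
Real data enter through standard mzML (parsed with pyteomics), with a JSON
sidecar mapping scan index to the dynamic-selection metadata (center,
starting width, accumulation time) that mzML cannot carry.  Demultiplexed
pseudo-spectra can be exported as MGF with the inferred precursor m/z.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .containers import PrecursorSpecies, ProductIon, ScanRecord, SelectionWindow
from .errors import SchemaError

__all__ = [
    "SCAN_TABLE_COLUMNS",
    "RunConfig",
    "write_scan_table",
    "read_scan_table",
    "read_mzml",
    "write_mgf",
    "load_config",
    "read_precursor_table",
]

logger = logging.getLogger(__name__)

SCAN_TABLE_COLUMNS = [
    "scan_id",
    "rt_s",
    "ms_level",
    "center_th",
    "start_width_th",
    "it_ms",
    "microscans",
    "mz",
    "intensity",
]


@dataclass(frozen=True)
class RunConfig:
    """Acquisition, noise and physics defaults for a simulated run."""

    width: float = 10.0  # Th
    overlap: float = 5.0  # Th
    mz_range: tuple[float, float] = (150.0, 1750.0)
    max_accumulation_time: float = 30.0  # ms
    agc_target: float = 3.0e4  # charges
    microscans: int = 1
    noise_rms: float = 0.01
    shot_noise: bool = False
    frequency: float = 1.1e6  # Hz
    r0: float = 4.0e-3  # m
    p13c: float = 0.011
    ppm_tol: float = 25.0
    grouping_tol: float = 0.6  # Th
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.width):
            raise SchemaError(f"need 0 <= overlap < width, got overlap={self.overlap}")
        for name in ("width", "max_accumulation_time", "agc_target", "frequency", "r0"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be positive")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise SchemaError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    if "mz_range" in data:
        data["mz_range"] = tuple(data["mz_range"])
    return RunConfig(**data)


def _fmt_mz(x: float) -> str:
    return f"{x:.6f}"


def _fmt_intensity(x: float) -> str:
    return f"{x:.6g}"


def write_scan_table(
    scans: Sequence[ScanRecord],
    path: Union[str, Path],
    metadata: Optional[dict] = None,
) -> None:
    """Write scans as TSV (one row per peak) with a JSON metadata sidecar.

    m/z is serialised with 6 decimal places, intensities with 6 significant
    figures (ample for 25 ppm matching at 2000 Th); column order is fixed
    and locale-independent.  Empty scans keep one row with blank mz and
    intensity so the round trip preserves them.
    """
    path = Path(path)
    lines = ["\t".join(SCAN_TABLE_COLUMNS)]
    for s in scans:
        prefix = (
            f"{s.scan_index}\t{s.retention_time:.4f}\t{s.ms_level}\t"
            f"{_fmt_mz(s.window.center)}\t{_fmt_mz(s.window.start_width)}\t"
            f"{s.accumulation_time:.6g}\t{s.microscans}"
        )
        if s.n_peaks == 0:
            lines.append(f"{prefix}\t\t")
        for mz, inten in zip(s.mzs, s.intensities):
            lines.append(f"{prefix}\t{_fmt_mz(mz)}\t{_fmt_intensity(inten)}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"n_scans": len(scans), "format": "dynaquad-scan-table-v1"}
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_scan_table(path: Union[str, Path]) -> list[ScanRecord]:
    """Read a TSV scan table back into validated ScanRecords.

    Row order is preserved; peaks are re-sorted by m/z per scan.  Schema
    violations (missing columns, negative intensities, non-monotone scan
    times) raise ``SchemaError`` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"mz": float, "intensity": float})
    missing = [c for c in SCAN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"scan table {path} lacks columns: {missing}")
    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise SchemaError(f"negative intensity at row {int(neg[0]) + 2} of {path}")

    scans: list[ScanRecord] = []
    last_rt_by_scan: list[tuple[int, float]] = []
    for scan_id, grp in df.groupby("scan_id", sort=False):
        first = grp.iloc[0]
        for col in ("rt_s", "ms_level", "center_th", "start_width_th", "it_ms", "microscans"):
            if grp[col].nunique() > 1:
                raise SchemaError(
                    f"scan {scan_id}: column {col} varies within one scan in {path}"
                )
        peaks = grp.dropna(subset=["mz"])
        window = SelectionWindow(
            center=float(first["center_th"]),
            start_width=float(first["start_width_th"]),
            accumulation_time=float(first["it_ms"]),
        )
        scans.append(
            ScanRecord(
                scan_index=int(scan_id),
                window=window,
                accumulation_time=float(first["it_ms"]),
                ms_level=int(first["ms_level"]),
                retention_time=float(first["rt_s"]),
                microscans=int(first["microscans"]),
                mzs=peaks["mz"].to_numpy(),
                intensities=peaks["intensity"].to_numpy(),
            )
        )
        last_rt_by_scan.append((int(scan_id), float(first["rt_s"])))
    for (id1, rt1), (id2, rt2) in zip(last_rt_by_scan, last_rt_by_scan[1:]):
        if rt2 < rt1:
            raise SchemaError(
                f"non-monotone retention time: scan {id2} at {rt2} s after scan {id1} at {rt1} s"
            )
    return scans


def _centroid_profile(mzs: np.ndarray, intens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local-maximum centroiding for profile-mode spectra."""
    if mzs.size < 3:
        return mzs, intens
    is_max = (intens[1:-1] > intens[:-2]) & (intens[1:-1] >= intens[2:]) & (intens[1:-1] > 0)
    idx = np.nonzero(is_max)[0] + 1
    return mzs[idx], intens[idx]


def read_mzml(
    path: Union[str, Path],
    window_map: Union[dict, str, Path],
) -> list[ScanRecord]:
    """Read an mzML file, attaching dynamic-selection metadata from a sidecar.

    ``window_map`` maps scan index (int, or its string form) to a mapping
    with keys ``center``, ``start_width`` and ``it_ms``; it may also be the
    path of a JSON file holding that mapping.  Scans absent from the map are
    skipped with a warning.  Profile-mode spectra are centroided by
    local-maximum picking (flagged in the log).

    The reader is a minimal namespace-agnostic mzML parser (spectrum index,
    ms level, scan start time, and the m/z / intensity binary arrays with
    optional zlib compression); vendor extensions are ignored.
    """
    if not isinstance(window_map, dict):
        window_map = json.loads(Path(window_map).read_text())
    scans: list[ScanRecord] = []
    n_skipped = 0
    for spectrum in _iter_mzml_spectra(path):
        idx = spectrum["index"]
        meta = window_map.get(idx, window_map.get(str(idx)))
        if meta is None:
            n_skipped += 1
            continue
        mzs, intens = spectrum["mzs"], spectrum["intensities"]
        if spectrum["profile_mode"]:
            mzs, intens = _centroid_profile(mzs, intens)
            logger.info("scan %d: profile mode, centroided by local maxima", idx)
        scans.append(
            ScanRecord(
                scan_index=idx,
                window=SelectionWindow(
                    center=float(meta["center"]),
                    start_width=float(meta["start_width"]),
                    accumulation_time=float(meta["it_ms"]),
                ),
                accumulation_time=float(meta["it_ms"]),
                ms_level=spectrum["ms_level"],
                retention_time=spectrum["rt_s"],
                mzs=mzs,
                intensities=intens,
            )
        )
    if n_skipped:
        logger.warning("skipped %d mzML scans absent from the window sidecar", n_skipped)
    return scans


def _iter_mzml_spectra(path: Union[str, Path]):
    """Yield dicts of the spectrum fields this package needs from an mzML file."""
    import base64
    import zlib

    from lxml import etree

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    for _, elem in etree.iterparse(str(path), events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        out = {
            "index": int(elem.get("index", -1)),
            "ms_level": 2,
            "rt_s": 0.0,
            "profile_mode": False,
            "mzs": np.empty(0),
            "intensities": np.empty(0),
        }
        for cv in elem.iter():
            if local(cv.tag) != "cvParam":
                continue
            name = cv.get("name", "")
            if name == "ms level":
                out["ms_level"] = int(cv.get("value"))
            elif name == "profile spectrum":
                out["profile_mode"] = True
            elif name == "scan start time":
                rt = float(cv.get("value"))
                unit = cv.get("unitName", "minute")
                out["rt_s"] = rt * 60.0 if unit.startswith("min") else rt
        for array in elem.iter():
            if local(array.tag) != "binaryDataArray":
                continue
            dtype, compressed, kind = np.float64, False, None
            for cv in array.iter():
                if local(cv.tag) != "cvParam":
                    continue
                name = cv.get("name", "")
                if name == "32-bit float":
                    dtype = np.float32
                elif name == "zlib compression":
                    compressed = True
                elif name in ("m/z array", "intensity array"):
                    kind = name
            node = next((c for c in array.iter() if local(c.tag) == "binary"), None)
            if kind is None or node is None or not node.text:
                continue
            raw = base64.b64decode(node.text)
            if compressed:
                raw = zlib.decompress(raw)
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            out["mzs" if kind == "m/z array" else "intensities"] = values
        yield out
        elem.clear()


def write_mgf(result, path: Union[str, Path]) -> None:
    """Export pseudo-spectra as MGF, one block per inferred precursor."""
    from pyteomics import mgf as _mgf

    spectra = []
    for i, ps in enumerate(result.pseudo_spectra):
        spectra.append(
            {
                "m/z array": ps.product_mzs,
                "intensity array": ps.product_intensities,
                "params": {
                    "title": f"dynaquad pseudo-spectrum {i}",
                    "pepmass": (round(ps.precursor_mz, 6), round(ps.apex_intensity, 4)),
                },
            }
        )
    _mgf.write(spectra, output=str(path), file_mode="w")


def read_precursor_table(path: Union[str, Path]) -> list[PrecursorSpecies]:
    """Read a declared precursor population from TSV.

    Columns: ``mz``, ``charge``, ``intensity``; optional ``peptide_length``,
    ``rt_apex_s``/``rt_sigma_s`` (elution), and ``products`` as
    semicolon-separated ``mz:yield`` or ``mz:yield:carbons`` triples.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("mz", "charge", "intensity"):
        if col not in df.columns:
            raise SchemaError(f"precursor table lacks column {col!r}")
    precursors = []
    for i, row in df.iterrows():
        products = []
        raw = row.get("products")
        if isinstance(raw, str) and raw.strip():
            for part in raw.split(";"):
                fields = part.split(":")
                if len(fields) not in (2, 3):
                    raise SchemaError(f"row {i + 2}: malformed product spec {part!r}")
                products.append(
                    ProductIon(
                        mz=float(fields[0]),
                        yield_=float(fields[1]),
                        carbon_count=int(fields[2]) if len(fields) == 3 else None,
                    )
                )
        length = row.get("peptide_length")
        elution = None
        if "rt_apex_s" in df.columns and not pd.isna(row.get("rt_apex_s")):
            elution = (float(row["rt_apex_s"]), float(row["rt_sigma_s"]))
        precursors.append(
            PrecursorSpecies(
                mz=float(row["mz"]),
                charge=int(row["charge"]),
                intensity=float(row["intensity"]),
                peptide_length=None if pd.isna(length) else int(length),
                elution=elution,
                products=tuple(products),
            )
        )
    return precursors
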