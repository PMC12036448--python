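"""Readers and writers for MS/MS spectra (MGF, mzML) and aligned feature tables.

MGF parsing and writing go through :mod:`pyteomics.mgf`.  mzML support is a
compact reader/writer pair for the PSI 1.1 schema (MS2 scans, 32/64-bit
plain or zlib-compressed arrays), enough to round-trip centroided MS/MS
collections.

Feature tables are tab/comma-delimited matrices accompanied by a column-map
schema (dict or YAML) that names the feature id / m/z / RT columns and maps
each sample column to a group and matrix label.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _pymgf

from .spectra import Spectrum, SpectrumCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_mzml",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "feature_table_schema",
    "SchemaError",
]


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def _charge_polarity(charge_list) -> tuple[int, str | None]:
    """Interpret a pyteomics charge list -> (abs charge, polarity or None)."""
    if not charge_list:
        return 1, None
    c = int(charge_list[0])
    if c == 0:
        return 1, None
    return abs(c), "negative" if c < 0 else "positive"


def read_mgf(path, polarity: str | None = None) -> SpectrumCollection:
    """Read an MGF file into a :class:`SpectrumCollection`.

    One spectrum per ``BEGIN IONS`` block.  Polarity is inferred from the
    CHARGE sign (``1-`` and ``-1`` both parse as negative); the ``polarity``
    argument overrides per-file when CHARGE is absent or unsigned.  Blocks
    without PEPMASS are skipped with a warning; a malformed block raises an
    error naming the block index.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, entry in enumerate(reader):
            try:
                params = entry.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    logger.warning("MGF block %d in %s has no PEPMASS; skipped", idx, path.name)
                    continue
                charge, pol = _charge_polarity(params.get("charge"))
                pol = pol or polarity
                if pol is None:
                    raise ValueError("polarity not derivable from CHARGE and no override given")
                scan_id = str(params.get("title") or params.get("scans") or f"{path.stem}_scan{idx}")
                rt = params.get("rtinseconds")
                meta = {
                    k: v
                    for k, v in params.items()
                    if k not in {"pepmass", "charge", "title", "scans", "rtinseconds"}
                }
                spectra.append(
                    Spectrum(
                        scan_id=scan_id,
                        precursor_mz=float(pepmass[0]),
                        polarity=pol,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        retention_time=float(rt) if rt is not None else None,
                        charge=charge,
                        source_file=path.name,
                        metadata=meta,
                    )
                )
            except Exception as exc:  # noqa: BLE001 - re-raise with block context
                raise ValueError(f"malformed MGF block {idx} in {path}: {exc}") from exc
    return SpectrumCollection(spectra)


def write_mgf(collection: SpectrumCollection, path) -> None:
    """Write a collection to MGF, lossless for the fields the type carries."""
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    entries = []
    for s in collection:
        params: dict = {
            "title": s.scan_id,
            "pepmass": s.precursor_mz,
            "charge": f"{s.charge}{'-' if s.polarity == 'negative' else '+'}",
        }
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time
        for k, v in s.metadata.items():
            params.setdefault(k, v)
        entries.append({"m/z array": s.mz, "intensity array": s.intensity, "params": params})
    with open(path, "w") as fh:
        _pymgf.write(entries, fh, key_order=["title", "pepmass", "charge", "rtinseconds"])


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _cv_params(elem: ET.Element, ns: str) -> dict[str, str]:
    return {cv.get("name"): cv.get("value", "") for cv in elem.findall(f"{ns}cvParam")}


def _decode_binary_array(bda: ET.Element, ns: str, n: int) -> tuple[str, np.ndarray]:
    params = _cv_params(bda, ns)
    kind = "m/z" if "m/z array" in params else "intensity" if "intensity array" in params else ""
    binary = bda.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if values.size != n:
        raise ValueError(f"binary array length {values.size} != defaultArrayLength {n}")
    return kind, values


def read_mzml(path) -> SpectrumCollection:
    """Read the MS2 scans of an mzML (or indexedmzML) file.

    Only MS-level-2 scans are returned; polarity and retention time are read
    per scan (minutes converted to seconds).  Binary arrays may be 32- or
    64-bit floats, plain or zlib-compressed.  Profile-mode MS2 data raise an
    error instructing centroiding; a file without MS2 scans yields an empty
    collection with a warning.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    ns = root.tag.partition("}")[0] + "}" if root.tag.startswith("{") else ""
    spectra: list[Spectrum] = []
    for elem in root.iter(f"{ns}spectrum"):
        params = _cv_params(elem, ns)
        if params.get("ms level") != "2":
            continue
        if "profile spectrum" in params:
            raise ValueError(
                f"{path.name}: profile-mode MS2 data; centroid the file before reading"
            )
        if "negative scan" in params:
            pol = "negative"
        elif "positive scan" in params:
            pol = "positive"
        else:
            raise ValueError(f"{path.name}: scan {elem.get('id')!r} lacks polarity metadata")
        ion = elem.find(
            f"{ns}precursorList/{ns}precursor/{ns}selectedIonList/{ns}selectedIon"
        )
        if ion is None:
            raise ValueError(f"{path.name}: MS2 scan {elem.get('id')!r} lacks a selected ion")
        ion_params = _cv_params(ion, ns)
        charge = int(float(ion_params.get("charge state", 1) or 1))
        rt = None
        for scan in elem.findall(f"{ns}scanList/{ns}scan"):
            for cv in scan.findall(f"{ns}cvParam"):
                if cv.get("name") == "scan start time":
                    rt = float(cv.get("value"))
                    if str(cv.get("unitName", "second")).startswith("min"):
                        rt *= 60.0
        n = int(elem.get("defaultArrayLength", 0))
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            kind, values = _decode_binary_array(bda, ns, n)
            if kind:
                arrays[kind] = values
        if "m/z" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path.name}: scan {elem.get('id')!r} lacks peak arrays")
        spectra.append(
            Spectrum(
                scan_id=str(elem.get("id")),
                precursor_mz=float(ion_params["selected ion m/z"]),
                polarity=pol,
                mz=arrays["m/z"],
                intensity=arrays["intensity"],
                retention_time=rt,
                charge=charge,
                source_file=path.name,
            )
        )
    if not spectra:
        logger.warning("%s contains no MS2 scans", path.name)
    return SpectrumCollection(spectra)


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(collection: SpectrumCollection, path) -> None:
    """Write MS2 scans as a minimal plain (non-indexed) mzML 1.1 document.

    Arrays are uncompressed little-endian 64-bit floats; each scan carries
    ms level 2, centroid mode, polarity, selected-ion m/z, charge state and
    scan start time (seconds).  Readable by :func:`read_mzml`.
    """
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <cvList count="1">',
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        "  </cvList>",
        '  <run id="run1">',
        f'    <spectrumList count="{len(collection)}">',
    ]
    for i, s in enumerate(collection):
        pol_acc, pol_name = (
            ("MS:1000129", "negative scan")
            if s.polarity == "negative"
            else ("MS:1000130", "positive scan")
        )
        mz64, int64 = _b64_doubles(s.mz), _b64_doubles(s.intensity)
        rt = s.retention_time if s.retention_time is not None else 0.0
        lines += [
            f'      <spectrum index="{i}" id="{escape(s.scan_id, {chr(34): "&quot;"})}" defaultArrayLength="{s.n_peaks}">',
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>',
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
            f'        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>',
            '        <scanList count="1">',
            "          <scan>",
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>',
            "          </scan>",
            "        </scanList>",
            '        <precursorList count="1">',
            "          <precursor>",
            '            <selectedIonList count="1">',
            "              <selectedIon>",
            f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz!r}"/>',
            f'                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s.charge}"/>',
            "              </selectedIon>",
            "            </selectedIonList>",
            "          </precursor>",
            "        </precursorList>",
            '        <binaryDataArrayList count="2">',
            f'          <binaryDataArray encodedLength="{len(mz64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>',
            f"            <binary>{mz64}</binary>",
            "          </binaryDataArray>",
            f'          <binaryDataArray encodedLength="{len(int64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>',
            f"            <binary>{int64}</binary>",
            "          </binaryDataArray>",
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))
    # fail fast on malformed XML rather than at read time
    ET.fromstring(Path(path).read_text())


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """A feature-table schema does not match the file's columns."""


@dataclass
class FeatureTable:
    """Features x samples peak-area matrix with metadata.

    ``features`` is indexed by feature id with columns ``mz`` (Da), ``rt``
    (seconds) and optionally ``annotation``; ``samples`` is indexed by sample
    id with columns ``group`` and ``matrix``; ``areas`` is the non-negative
    features x samples matrix.  ``spectra`` optionally maps feature ids to a
    representative MS/MS spectrum (used for cross-matrix matching).
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    areas: pd.DataFrame
    spectra: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.areas.index) != list(self.features.index):
            raise ValueError("areas rows must match the feature index")
        if list(self.areas.columns) != list(self.samples.index):
            raise ValueError("areas columns must match the sample index")
        if (self.areas.to_numpy() < 0).any():
            bad = self.areas.stack()
            bad = bad[bad < 0]
            raise ValueError(f"negative peak areas at {list(bad.index[:5])}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["group"] == group])


def _load_schema(schema) -> dict:
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError("schema must be a mapping or a YAML file path")
    for key in ("feature_id", "mz", "rt", "samples"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    return schema


def read_feature_table(path, schema) -> FeatureTable:
    """Read a delimited feature table using a column-map ``schema``.

    ``schema`` maps ``feature_id``/``mz``/``rt`` (and optionally
    ``annotation``) to column names and ``samples`` to a mapping of sample
    column name -> ``{group: ..., matrix: ...}``.  Unmapped extra columns are
    ignored with a log message; a mapped column missing from the file raises
    :class:`SchemaError`; negative areas raise with the offending cells.
    """
    schema = _load_schema(schema)
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    sample_map = schema["samples"]
    mapped = [schema["feature_id"], schema["mz"], schema["rt"], *sample_map]
    if schema.get("annotation"):
        mapped.append(schema["annotation"])
    missing = [c for c in mapped if c not in df.columns]
    if missing:
        raise SchemaError(f"mapped column(s) {missing} not present in {path.name}")
    extra = [c for c in df.columns if c not in mapped]
    if extra:
        logger.info("%s: ignoring unmapped column(s) %s", path.name, extra)

    features = pd.DataFrame(
        {
            "mz": df[schema["mz"]].astype(float).to_numpy(),
            "rt": df[schema["rt"]].astype(float).to_numpy(),
        },
        index=pd.Index(df[schema["feature_id"]].astype(str), name="feature_id"),
    )
    if schema.get("annotation"):
        features["annotation"] = df[schema["annotation"]].to_numpy()
    samples = pd.DataFrame.from_dict(sample_map, orient="index")
    samples.index.name = "sample_id"
    if "group" not in samples.columns:
        raise SchemaError("every sample mapping needs a 'group' label")
    if "matrix" not in samples.columns:
        samples["matrix"] = ""
    areas = df[list(sample_map)].astype(float)
    areas.index = features.index
    neg = areas.stack()
    neg = neg[neg < 0]
    if len(neg):
        raise ValueError(f"negative areas at (feature, sample) cells {list(neg.index[:10])}")
    return FeatureTable(features=features, samples=samples[["group", "matrix"]], areas=areas)


def feature_table_schema(table: FeatureTable) -> dict:
    """Schema dict under which :func:`write_feature_table` output re-reads."""
    return {
        "feature_id": "feature_id",
        "mz": "mz",
        "rt": "rt",
        **({"annotation": "annotation"} if "annotation" in table.features.columns else {}),
        "samples": {
            sid: {"group": row["group"], "matrix": row["matrix"]}
            for sid, row in table.samples.iterrows()
        },
    }


def write_feature_table(table: FeatureTable, path, schema_path=None) -> None:
    """Write the table as TSV/CSV; optionally write its YAML schema alongside."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = table.features.reset_index()
    df = pd.concat([df, table.areas.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep=sep, index=False)
    if schema_path is not None:
        with open(schema_path, "w") as fh:
            yaml.safe_dump(feature_table_schema(table), fh, sort_keys=False)
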