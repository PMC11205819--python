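"""Core data types and I/O for single-cell Raman spectra and packaged reference tables.

A :class:`Spectrum` is one cell's Raman trace (wavenumber axis in cm^-1 plus
intensity in arbitrary units); a :class:`Ramanome` is the collection of spectra
acquired from one population under one condition, the unit on which all
statistics are computed.  Band-reference tables give the expected Raman band
centers for *Durusdinium* sp. (a Symbiodiniaceae dinoflagellate) and
*Ruegeria* sp. MR31c (a coral-associated alphaproteobacterium), including the
red-shifted positions that nitrogen-associated bands move to after assimilation
of a ^15N-labeled substrate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "Ramanome",
    "BandReference",
    "IsolateRecord",
    "read_spectrum",
    "write_spectrum",
    "read_ramanome_dir",
    "write_ramanome_dir",
    "load_band_reference",
    "load_isolate_table",
]

Organism = Literal["durusdinium", "ruegeria", "blank"]
Isotope = Literal["N14", "N15", "none"]

# sha256 of the packaged isolate fixture; guards against silent corruption.
_ISOLATES_SHA256 = "8ad9c7d6a2414ad6e675f0b4db3bc576e2bbeb475564cbd2610f5f37b7875d85"


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.array(a, dtype=float, copy=True)
    a.flags.writeable = False
    return a


@dataclass(frozen=True)
class Spectrum:
    """One single-cell Raman trace.

    Parameters
    ----------
    wavenumber_cm1
        Strictly increasing axis, finite and positive, in cm^-1.
    intensity
        Same length as the axis, arbitrary units.
    meta
        Free-form metadata; conventional keys are ``cell_id``, ``organism``
        (``durusdinium`` / ``ruegeria`` / ``blank``), ``isotope``
        (``N14`` / ``N15`` / ``none``) and ``replicate``.
    """

    wavenumber_cm1: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = _as_readonly(self.wavenumber_cm1)
        y = _as_readonly(self.intensity)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumber and intensity must be 1-D")
        if len(x) != len(y):
            raise ValueError(
                f"axis and intensity lengths differ ({len(x)} vs {len(y)})"
            )
        if len(x) == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.isfinite(x)) or not np.all(x > 0):
            raise ValueError("wavenumbers must be finite and > 0")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        if np.any(np.diff(x) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "wavenumber_cm1", x)
        object.__setattr__(self, "intensity", y)

    def __len__(self) -> int:
        return len(self.wavenumber_cm1)

    def with_intensity(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        """Return a copy with new intensities (axis and metadata preserved)."""
        meta = {**self.meta, **meta_updates}
        return Spectrum(self.wavenumber_cm1, intensity, meta)

    @property
    def cell_id(self) -> str:
        return str(self.meta.get("cell_id", ""))


@dataclass(frozen=True)
class Ramanome:
    """A labeled collection of single-cell spectra from one condition.

    ``blanks`` are medium-only acquisitions taken alongside the cells
    (4 blank regions per 20 cells in the standard protocol) used for
    background subtraction.
    """

    spectra: tuple
    condition: dict
    blanks: tuple = ()

    def __init__(
        self,
        spectra: Iterable[Spectrum],
        condition: dict,
        blanks: Iterable[Spectrum] = (),
    ) -> None:
        object.__setattr__(self, "spectra", tuple(spectra))
        object.__setattr__(self, "condition", dict(condition))
        object.__setattr__(self, "blanks", tuple(blanks))
        organisms = {s.meta.get("organism") for s in self.spectra} - {None}
        isotopes = {s.meta.get("isotope") for s in self.spectra} - {None}
        if len(organisms) > 1:
            raise ValueError(f"mixed organisms in one ramanome: {organisms}")
        if len(isotopes) > 1:
            raise ValueError(f"mixed isotope labels in one ramanome: {isotopes}")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def organism(self) -> str:
        return str(self.condition.get("organism", ""))

    @property
    def isotope(self) -> str:
        return str(self.condition.get("isotope", ""))


class BandReference:
    """Table of expected Raman band centers with assignments.

    Wraps a DataFrame with columns ``center_cm1``, ``component``,
    ``assignment``, ``nitrogen_associated`` and ``n15_center_cm1`` (NaN where
    the band does not shift).  Rows with an ^15N center are the
    isotope-sensitive bands; every such center lies below the ^14N center
    (heavier isotope -> lower vibrational frequency -> red shift).
    """

    def __init__(self, table: pd.DataFrame, organism: str = ""):
        required = {
            "center_cm1",
            "component",
            "assignment",
            "nitrogen_associated",
            "n15_center_cm1",
        }
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"band table missing columns: {sorted(missing)}")
        t = table.reset_index(drop=True).copy()
        t["center_cm1"] = t["center_cm1"].astype(float)
        t["n15_center_cm1"] = t["n15_center_cm1"].astype(float)
        t["nitrogen_associated"] = t["nitrogen_associated"].astype(bool)
        if t["center_cm1"].duplicated().any():
            raise ValueError("duplicate band centers in reference table")
        shifted = t["n15_center_cm1"].notna()
        if not (t.loc[shifted, "n15_center_cm1"] < t.loc[shifted, "center_cm1"]).all():
            raise ValueError("every n15 center must lie below its n14 center")
        if not t.loc[shifted, "nitrogen_associated"].all():
            raise ValueError("bands with an n15 center must be nitrogen_associated")
        self.table = t
        self.organism = organism

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return iter(self.table.itertuples(index=False))

    @property
    def centers(self) -> np.ndarray:
        return self.table["center_cm1"].to_numpy()

    def nearest(self, center_cm1: float) -> pd.Series:
        """Row of the reference band closest (in ^14N position) to ``center_cm1``."""
        i = int(np.argmin(np.abs(self.centers - center_cm1)))
        return self.table.iloc[i]

    def band_label(self, row) -> str:
        return f"{row.center_cm1:g} {row.assignment}"


@dataclass(frozen=True)
class IsolateRecord:
    """One cultured coral-associated bacterial isolate (16S rDNA identified)."""

    no: str
    genus: str
    name: str
    accession: str
    medium: str
    coral: str
    identity_pct: float

    def __post_init__(self) -> None:
        if not 0 < self.identity_pct <= 100:
            raise ValueError(f"identity_pct out of (0, 100]: {self.identity_pct}")


# ---------------------------------------------------------------------------
# Spectrum file I/O: two-column ASCII with '#' comments; CSV or TSV dialects.
# Metadata travels in a sidecar JSON (<file>.json) because plain two-column
# instrument exports carry no standard header.
# ---------------------------------------------------------------------------

_DELIMS = {"csv": ",", "tsv": "\t", "two_column_ascii": None}


def read_spectrum(
    path: str | Path,
    dialect: Literal["csv", "tsv", "two_column_ascii"] | None = None,
) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text file.

    Descending axes are accepted and resorted ascending with intensities
    co-permuted.  ``dialect=None`` sniffs the delimiter.  A sidecar
    ``<path>.json`` file, if present, populates the metadata.
    """
    path = Path(path)
    if dialect is not None and dialect not in _DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        delim = _DELIMS.get(dialect) if dialect else ("," if "," in line else None)
        parts = line.split(delim)
        parts = [p for p in parts if p != ""]
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric row {raw!r}") from exc
    if not xs:
        raise ValueError(f"{path}: no data rows")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(np.unique(x)) != len(x):
        raise ValueError(f"{path}: duplicate wavenumbers")
    order = np.argsort(x)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Spectrum(x[order], y[order], meta)


def write_spectrum(
    spectrum: Spectrum,
    path: str | Path,
    dialect: Literal["csv", "tsv", "two_column_ascii"] = "csv",
    sidecar: bool = True,
) -> Path:
    """Write a spectrum as full-precision two-column text (round-trips exactly)."""
    if dialect not in _DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    delim = _DELIMS[dialect] or " "
    lines = ["# wavenumber_cm1{0}intensity".format(delim)]
    for x, y in zip(spectrum.wavenumber_cm1, spectrum.intensity):
        lines.append(f"{float(x)!r}{delim}{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")
    if sidecar and spectrum.meta:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(spectrum.meta, sort_keys=True, indent=1)
        )
    return path


def write_ramanome_dir(
    ramanome: Ramanome, directory: str | Path, dialect: str = "csv"
) -> Path:
    """Write all spectra of a ramanome into a directory with a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"csv": ".csv", "tsv": ".tsv", "two_column_ascii": ".txt"}[dialect]
    entries = []
    for kind, group in (("cell", ramanome.spectra), ("blank", ramanome.blanks)):
        for i, s in enumerate(group):
            name = f"{kind}_{s.meta.get('cell_id', i)}{ext}"
            write_spectrum(s, directory / name, dialect=dialect)
            entries.append({"file": name, "kind": kind, "meta": s.meta})
    manifest = {
        "condition": ramanome.condition,
        "dialect": dialect,
        "spectra": entries,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1)
    )
    return directory


def read_ramanome_dir(directory: str | Path) -> Ramanome:
    """Read a ramanome directory written by :func:`write_ramanome_dir`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    dialect = manifest.get("dialect", "csv")
    cells, blanks = [], []
    for entry in manifest["spectra"]:
        s = read_spectrum(directory / entry["file"], dialect=dialect)
        s = Spectrum(s.wavenumber_cm1, s.intensity, {**entry.get("meta", {}), **s.meta})
        (blanks if entry.get("kind") == "blank" else cells).append(s)
    return Ramanome(cells, manifest["condition"], blanks)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("ramansip").joinpath("data", name)


def load_band_reference(
    organism: Literal["durusdinium", "ruegeria"], extended: bool = False
) -> BandReference:
    """Load the packaged band-reference table for an organism.

    The *Durusdinium* table has 20 bands and the *Ruegeria* table 11.  With
    ``extended=True`` the *Durusdinium* table additionally includes the
    amide III protein band at 1240 cm^-1, whose ^15N red shift is part of the
    co-culture labeling signature but which is not in the base 20-band table;
    the SIP pipeline uses the extended table by default.
    """
    files = {"durusdinium": "durusdinium_bands.tsv", "ruegeria": "ruegeria_bands.tsv"}
    if organism not in files:
        raise ValueError(f"unknown organism {organism!r}; expected one of {sorted(files)}")
    table = pd.read_csv(_data_path(files[organism]), sep="\t")
    if extended and organism == "durusdinium":
        extra = pd.read_csv(_data_path("durusdinium_bands_extended.tsv"), sep="\t")
        table = (
            pd.concat([table, extra], ignore_index=True)
            .sort_values("center_cm1")
            .reset_index(drop=True)
        )
    return BandReference(table, organism=organism)


def load_isolate_table() -> list[IsolateRecord]:
    """Load the packaged table of 41 cultured coral-associated isolates."""
    path = _data_path("isolates.tsv")
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _ISOLATES_SHA256:
        raise ValueError(
            f"isolate fixture checksum mismatch (got {digest}); fixture corrupted?"
        )
    table = pd.read_csv(path, sep="\t")
    records = [
        IsolateRecord(
            no=row.no,
            genus=row.genus,
            name=row.name,
            accession=row.accession,
            medium=row.medium,
            coral=row.coral,
            identity_pct=float(row.identity_pct),
        )
        for row in table.itertuples(index=False)
    ]
    if len(records) != 41:
        raise ValueError(f"expected 41 isolate records, found {len(records)}")
    return records
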