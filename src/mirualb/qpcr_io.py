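"""Data model and file I/O for censored qPCR panels and sample annotations.

qPCR instruments report a quantification cycle (Cq) per species per sample:
the cycle at which fluorescence crosses threshold, so lower Cq means higher
abundance.  Species whose signal never crosses threshold within the run's
maximum cycle count are *non-detects* (right-censored); by convention these
are imputed at the maximum cycle count (40 by default) and tracked in a
boolean detection mask.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "SampleTable",
    "ReferencePanel",
    "DEFAULT_NONDETECT_TOKENS",
    "DEFAULT_MAX_CYCLES",
    "read_cq_table",
    "write_cq_table",
    "load_table1_fixture",
    "load_table2_fixture",
    "summarize_cohort",
]

DEFAULT_MAX_CYCLES = 40
DEFAULT_NONDETECT_TOKENS = ("NA", "ND", "Undetermined", "")

#: Canonical reference panel used for normalization: three miRNAs, three
#: small RNAs and an exogenous spike-in control.
DEFAULT_REFERENCE_SPECIES = (
    "miR-423-5p",
    "miR-103",
    "miR-191",
    "U6",
    "SNORD38B",
    "SNORD38A",
)
DEFAULT_SPIKE_IN = "UniSp3"


def _round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (printed-table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CqMatrix:
    """A species x samples matrix of Cq values with a detection mask.

    Non-detected entries carry ``cq == max_cycles`` (the censoring bound);
    ``detected`` records which entries are genuine measurements.
    """

    species_ids: list[str]
    sample_ids: list[str]
    cq: np.ndarray
    detected: np.ndarray
    max_cycles: int = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        self.cq = np.asarray(self.cq, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.cq.shape != self.detected.shape:
            raise ValueError("cq and detected must have identical shapes")
        if self.cq.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValueError("cq shape does not match id lists")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.impute_nondetects()
        if np.any(self.cq > self.max_cycles):
            i, j = np.argwhere(self.cq > self.max_cycles)[0]
            raise ValueError(
                f"Cq value {self.cq[i, j]} at species {self.species_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} exceeds max_cycles={self.max_cycles}"
            )

    def impute_nondetects(self) -> None:
        """Set every non-detected cell to the censoring bound (idempotent)."""
        self.cq[~self.detected] = float(self.max_cycles)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def species_index(self, species: str) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in matrix") from None

    def detection_fraction(self) -> pd.Series:
        """Fraction of samples in which each species was detected."""
        return pd.Series(self.detected.mean(axis=1), index=self.species_ids)

    def subset_species(self, species: Sequence[str]) -> "CqMatrix":
        idx = [self.species_index(s) for s in species]
        return CqMatrix(
            list(species),
            list(self.sample_ids),
            self.cq[idx].copy(),
            self.detected[idx].copy(),
            self.max_cycles,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.cq, index=self.species_ids, columns=self.sample_ids)

    def copy(self) -> "CqMatrix":
        return CqMatrix(
            list(self.species_ids),
            list(self.sample_ids),
            self.cq.copy(),
            self.detected.copy(),
            self.max_cycles,
        )


_GROUPS = ("N", "IMA", "PMA")
_FLAG_COLS = ("cad", "stroke", "pvd", "neuropathy", "retinopathy", "htn")


@dataclass
class SampleTable:
    """Per-sample clinical annotations: group (N / IMA / PMA), sex, age,
    glycated hemoglobin, diabetes duration, visit cycle and comorbidity flags.

    ``collapsed_group`` merges intermittent and persistent microalbuminuria
    into a single MA class, the contrast the prognostic analysis uses.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample table")
        bad = set(df["group"]) - set(_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not set(df["sex"]) <= {"M", "F"}:
            raise ValueError("sex must be 'M' or 'F'")
        df["collapsed_group"] = np.where(df["group"].isin(["IMA", "PMA"]), "MA", "N")
        for col in ("age", "duration"):
            if col in df and (pd.to_numeric(df[col]) <= 0).any():
                raise ValueError(f"{col} must be positive")
        for col in _FLAG_COLS:
            if col in df and df[col].dtype == object:
                df[col] = df[col].map({"+": True, "-": False, True: True, False: False})
        self.frame = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    @property
    def n(self) -> int:
        return len(self.frame)

    def group_labels(self) -> np.ndarray:
        """Collapsed MA/N labels, aligned with ``ids``."""
        return self.frame["collapsed_group"].to_numpy()

    def sex_labels(self) -> np.ndarray:
        return self.frame["sex"].to_numpy()

    def subset(self, ids: Sequence[str]) -> "SampleTable":
        df = self.frame.set_index("id").loc[[str(i) for i in ids]].reset_index()
        return SampleTable(df)

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None) -> "SampleTable":
        sep = sep if sep is not None else _sniff_sep(path)
        return cls(pd.read_csv(path, sep=sep, comment="#"))

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        out = self.frame.copy()
        for col in _FLAG_COLS:
            if col in out:
                out[col] = out[col].map({True: "+", False: "-"})
        out.drop(columns=["collapsed_group"]).to_csv(path, sep=sep, index=False)


@dataclass
class ReferencePanel:
    """Reference species used to compute per-sample normalization factors.

    ``members`` maps each reference species to the matrix row ids holding its
    replicate wells (default: the species is a single row).  ``panel_assignment``
    maps every assayed species to a panel label; single-panel by default.
    """

    reference_species: list[str] = field(
        default_factory=lambda: list(DEFAULT_REFERENCE_SPECIES)
    )
    spike_in: str = DEFAULT_SPIKE_IN
    panel_assignment: Mapping[str, str] | None = None
    members: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        if self.spike_in in self.reference_species:
            raise ValueError("spike-in control must not be a reference species")
        if self.members is None:
            self.members = {s: [s] for s in self.reference_species}

    def panel_of(self, species: str) -> str:
        if self.panel_assignment is None:
            return "panel1"
        return self.panel_assignment.get(species, "panel1")

    def panels(self) -> list[str]:
        if self.panel_assignment is None:
            return ["panel1"]
        return sorted(set(self.panel_assignment.values()) | {"panel1"})

    def validate_against(self, cq: CqMatrix) -> None:
        rows = set(cq.species_ids)
        for ref in self.reference_species:
            missing = [m for m in self.members[ref] if m not in rows]
            if missing:
                raise KeyError(
                    f"reference species {ref!r}: rows {missing} absent from Cq matrix"
                )

    @classmethod
    def for_matrix(cls, cq: "CqMatrix") -> "ReferencePanel":
        """Default panel with replicate rows discovered by name.

        A matrix row belongs to reference species R when its id is exactly
        R or R plus a ``_r<k>`` replicate suffix.
        """
        members = {}
        for ref in DEFAULT_REFERENCE_SPECIES:
            rows = [
                s for s in cq.species_ids
                if s == ref or s.startswith(ref + "_r")
            ]
            if rows:
                members[ref] = rows
        return cls(
            reference_species=list(members),
            spike_in=DEFAULT_SPIKE_IN,
            members=members,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferencePanel":
        """Read a panel file with columns species, role (reference|spike_in),
        and optionally panel."""
        df = pd.read_csv(path, sep=_sniff_sep(path))
        refs = list(df.loc[df["role"] == "reference", "species"])
        spikes = list(df.loc[df["role"] == "spike_in", "species"])
        assignment = None
        if "panel" in df.columns:
            assignment = dict(zip(df["species"], df["panel"]))
        return cls(
            reference_species=refs,
            spike_in=spikes[0] if spikes else DEFAULT_SPIKE_IN,
            panel_assignment=assignment,
        )


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    return "\t" if "\t" in first else ","


def read_cq_table(
    path: str | Path | io.StringIO,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    nondetect_tokens: Iterable[str] = DEFAULT_NONDETECT_TOKENS,
    sep: str | None = None,
) -> CqMatrix:
    """Read a delimited species x samples Cq table.

    Cells holding any of ``nondetect_tokens`` (case-sensitive, surrounding
    whitespace ignored) are recorded as non-detected and imputed at
    ``max_cycles``.  Input row/column order is preserved.
    """
    text = path.getvalue() if isinstance(path, io.StringIO) else Path(path).read_text()
    if sep is None:
        first = next(
            (ln for ln in text.splitlines() if ln and not ln.startswith("#")), ""
        )
        sep = "\t" if "\t" in first else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, comment="#")
    tokens = {t.strip() for t in nondetect_tokens}
    species = [str(s) for s in df.index]
    # pandas silently renames duplicate columns, so check the raw header
    header = next(ln for ln in text.splitlines() if ln and not ln.startswith("#"))
    samples = [c.strip() for c in header.split(sep)[1:]]
    if len(set(species)) != len(species):
        raise ValueError("duplicate species ids in Cq table")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in Cq table")
    raw = df.to_numpy()
    cq = np.full(raw.shape, float(max_cycles))
    detected = np.ones(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in tokens:
                detected[i, j] = False
                continue
            val = float(cell)
            if val > max_cycles:
                raise ValueError(
                    f"Cq {val} at species {species[i]!r}, sample {samples[j]!r} "
                    f"exceeds max_cycles={max_cycles}"
                )
            cq[i, j] = val
    return CqMatrix(species, samples, cq, detected, max_cycles)


def write_cq_table(
    cq: CqMatrix,
    path: str | Path | io.StringIO,
    nondetect_token: str = "NA",
    sep: str = "\t",
    header_comment: str | None = None,
) -> None:
    """Write a CqMatrix back to delimited text; non-detects become the token.

    Detected values are written with :func:`repr` so a read round-trips
    bitwise.
    """
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append(sep.join(["species", *cq.sample_ids]))
    for i, sp in enumerate(cq.species_ids):
        cells = [
            repr(float(cq.cq[i, j])) if cq.detected[i, j] else nondetect_token
            for j in range(cq.n_samples)
        ]
        lines.append(sep.join([sp, *cells]))
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.StringIO):
        path.write(text)
    else:
        Path(path).write_text(text)


def _fixture_path(name: str):
    return resources.files("mirualb.data").joinpath(name)


def load_table1_fixture() -> SampleTable:
    """The 27-patient cohort annotation table packaged with the library
    (10 never-progressors, 17 future microalbuminuria)."""
    with resources.as_file(_fixture_path("table1.tsv")) as p:
        return SampleTable.from_file(p, sep="\t")


def load_table2_fixture() -> pd.DataFrame:
    """Packaged prognostic-signature coefficient table.

    Returns a frame indexed by predictor name with columns
    ``concentration_only`` and ``concentration_binding`` (log-odds per
    feature unit; NaN where a predictor is absent from a model).  Predictor
    names carry an ``" X Women"`` suffix for gender-interaction terms.
    """
    with resources.as_file(_fixture_path("table2.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    return df.astype(float)


def summarize_cohort(samples: SampleTable) -> pd.DataFrame:
    """Per-collapsed-group counts and medians of age, duration and HbA1c.

    Medians are reported to one decimal, rounding half away from zero to
    match printed-table conventions.  Empty groups are omitted with a
    warning.
    """
    if samples.n == 0:
        raise ValueError("sample table is empty")
    rows = {}
    for grp in ("N", "MA"):
        sub = samples.frame[samples.frame["collapsed_group"] == grp]
        if len(sub) == 0:
            warnings.warn(f"group {grp!r} is empty and was omitted", stacklevel=2)
            continue
        rows[grp] = {
            "n": len(sub),
            "n_male": int((sub["sex"] == "M").sum()),
            "n_female": int((sub["sex"] == "F").sum()),
            "median_age": _round_half_away(float(sub["age"].median())),
            "median_duration": _round_half_away(float(sub["duration"].median())),
            "median_hba1c": _round_half_away(float(sub["hba1c"].median())),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
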