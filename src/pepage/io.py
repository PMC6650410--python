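"""File formats and in-memory containers for the CE-MS peptidomics pipeline.

Every file the pipeline reads or writes is tab-separated UTF-8 text with a
``.`` decimal separator and the literal string ``NA`` for a missing amplitude
cell.  Peptide masses are stored in daltons rounded to 4 decimals, CE
migration times in minutes rounded to 2 decimals; amplitudes are written with
shortest round-tripping ``repr`` so that read(write(x)) == x exactly.

Containers
----------
``PeptideObservation``
    One detected peptide in one sample: monoisotopic mass [Da], normalized CE
    migration time [min] and signal amplitude [arbitrary units].
``CohortDesign``
    Maps each sample to an (age group, treatment) pair and carries the
    explicit ordering of age groups (young -> old) that screening and
    classification rely on.
``MatchedMatrix``
    The master peptide list (consensus mass and migration time per master
    peptide) crossed with per-sample amplitudes; unobserved cells are NaN.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MISSING = "NA"
MASS_DECIMALS = 4
TIME_DECIMALS = 2

PROFILE_COLUMNS = ("id", "mass", "migration_time", "amplitude")


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


@dataclass(frozen=True, slots=True)
class PeptideObservation:
    """A single detected peptide in a single sample.

    Parameters
    ----------
    local_id : str
        Identifier local to the sample's peptide list.
    mass_da : float
        Monoisotopic mass in daltons (> 0).
    migration_min : float
        Normalized CE migration time in minutes (> 0).
    amplitude : float
        Signal intensity in arbitrary units (>= 0).
    """

    local_id: str
    mass_da: float
    migration_min: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.mass_da > 0:
            raise ValidationError(f"mass_da must be > 0, got {self.mass_da!r}")
        if not self.migration_min > 0:
            raise ValidationError(
                f"migration_min must be > 0, got {self.migration_min!r}"
            )
        if not self.amplitude >= 0:
            raise ValidationError(f"amplitude must be >= 0, got {self.amplitude!r}")


def read_peptide_profile(path, mass_unit: str = "Da") -> list[PeptideObservation]:
    """Read one per-sample peptide list.

    The file must carry a header naming the columns ``id``, ``mass``,
    ``migration_time`` and ``amplitude`` (any order, extra columns ignored).
    ``mass_unit`` declares the unit of the mass column: ``"Da"`` (stored
    as-is) or ``"kDa"`` (multiplied by 1000 on read).
    """
    if mass_unit not in ("Da", "kDa"):
        raise FormatError(f"mass_unit must be 'Da' or 'kDa', got {mass_unit!r}")
    scale = 1000.0 if mass_unit == "kDa" else 1.0
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header row required") from None
        idx = {}
        for col in PROFILE_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
            idx[col] = header.index(col)
        out: list[PeptideObservation] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                obs = PeptideObservation(
                    local_id=row[idx["id"]],
                    mass_da=float(row[idx["mass"]]) * scale,
                    migration_min=float(row[idx["migration_time"]]),
                    amplitude=float(row[idx["amplitude"]]),
                )
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            out.append(obs)
    return out


def write_peptide_profile(
    observations: Iterable[PeptideObservation], path, mass_unit: str = "Da"
) -> None:
    """Write a per-sample peptide list in the pipeline TSV dialect."""
    if mass_unit not in ("Da", "kDa"):
        raise FormatError(f"mass_unit must be 'Da' or 'kDa', got {mass_unit!r}")
    scale = 0.001 if mass_unit == "kDa" else 1.0
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for obs in observations:
            mass = obs.mass_da * scale
            decimals = MASS_DECIMALS + (3 if mass_unit == "kDa" else 0)
            fh.write(
                f"{obs.local_id}\t{round(mass, decimals)}\t"
                f"{round(obs.migration_min, TIME_DECIMALS)}\t{_fmt(obs.amplitude)}\n"
            )


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

DEFAULT_TREATMENT = "control"


@dataclass(frozen=True)
class CohortDesign:
    """Sample -> (age group, treatment) bookkeeping.

    ``age_order`` is the explicit young-to-old ordering of age-group labels;
    every downstream "per age step" statement refers to consecutive entries
    of this list.
    """

    samples: tuple[str, ...]
    age_group: Mapping[str, str]
    treatment: Mapping[str, str]
    age_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if list(self.samples).count(s) > 1})
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        for s in self.samples:
            if s not in self.age_group or s not in self.treatment:
                raise ValidationError(f"sample {s!r} missing group assignment")
            if self.age_group[s] not in self.age_order:
                raise ValidationError(
                    f"sample {s!r} has unknown age label {self.age_group[s]!r}; "
                    f"declared order is {list(self.age_order)}"
                )
        if len(self.age_order) != len(set(self.age_order)):
            raise ValidationError("age_order contains duplicates")

    @property
    def treatments(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.samples:
            t = self.treatment[s]
            if t not in seen:
                seen.append(t)
        return tuple(seen)

    def samples_in(self, age: str | None = None, treatment: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if age is not None and self.age_group[s] != age:
                continue
            if treatment is not None and self.treatment[s] != treatment:
                continue
            out.append(s)
        return out

    def group_sizes(self) -> dict[tuple[str, str], int]:
        sizes: dict[tuple[str, str], int] = {}
        for s in self.samples:
            key = (self.age_group[s], self.treatment[s])
            sizes[key] = sizes.get(key, 0) + 1
        return sizes


def read_cohort_design(path, age_order: Sequence[str] | None = None) -> CohortDesign:
    """Read a 2- or 3-column design table (sample, age_group[, treatment]).

    The age ordering is taken from (in precedence order): the ``age_order``
    argument, a ``# age_order: a,b,c`` comment line, or first appearance in
    the file.
    """
    path = Path(path)
    samples: list[str] = []
    ages: dict[str, str] = {}
    treats: dict[str, str] = {}
    declared: list[str] | None = list(age_order) if age_order is not None else None
    with path.open("r", encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("age_order:") and declared is None:
                    declared = [a.strip() for a in body[len("age_order:"):].split(",") if a.strip()]
                continue
            row = line.split("\t")
            if header is None:
                header = row
                if len(header) < 2 or header[0] != "sample_id" or header[1] != "age_group":
                    raise FormatError(
                        f"{path}: header must start with 'sample_id\\tage_group', got {header}"
                    )
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >=2 columns")
            sid, age = row[0], row[1]
            if sid in ages:
                raise ValidationError(f"{path}: duplicate sample id {sid!r} (line {lineno})")
            samples.append(sid)
            ages[sid] = age
            treats[sid] = row[2] if len(row) > 2 and row[2] else DEFAULT_TREATMENT
    if header is None:
        raise FormatError(f"{path}: empty design file")
    if declared is None:
        declared = []
        for s in samples:
            if ages[s] not in declared:
                declared.append(ages[s])
    return CohortDesign(
        samples=tuple(samples),
        age_group=ages,
        treatment=treats,
        age_order=tuple(declared),
    )


def write_cohort_design(design: CohortDesign, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# age_order: " + ",".join(design.age_order) + "\n")
        fh.write("sample_id\tage_group\ttreatment\n")
        for s in design.samples:
            fh.write(f"{s}\t{design.age_group[s]}\t{design.treatment[s]}\n")


# ---------------------------------------------------------------------------
# Matched matrix
# ---------------------------------------------------------------------------


@dataclass
class MatchedMatrix:
    """Master peptide list x samples amplitude matrix with explicit missingness.

    ``peptides`` is indexed by integer ``master_id`` (assigned 1..K in
    ascending consensus-mass order) with columns ``mass_da`` and
    ``migration_min`` (the amplitude-weighted consensus coordinates of the
    cluster members).  ``amplitudes`` shares the index; its columns are
    sample ids and unobserved cells are NaN.
    """

    peptides: pd.DataFrame
    amplitudes: pd.DataFrame
    match_stats: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if list(self.peptides.index) != list(self.amplitudes.index):
            raise ValidationError("peptides and amplitudes must share an index")
        for col in ("mass_da", "migration_min"):
            if col not in self.peptides.columns:
                raise ValidationError(f"peptides table missing column {col!r}")
        # the on-disk dialect keeps 4 / 2 decimals; enforce at construction so
        # round-trips are exact
        self.peptides = self.peptides.copy()
        self.peptides["mass_da"] = self.peptides["mass_da"].round(MASS_DECIMALS)
        self.peptides["migration_min"] = self.peptides["migration_min"].round(TIME_DECIMALS)

    @property
    def master_ids(self) -> list[int]:
        return list(self.peptides.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.amplitudes.columns)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def values_for(self, samples: Sequence[str]) -> np.ndarray:
        """Amplitude array (peptides x samples) for the given sample subset."""
        return self.amplitudes.loc[:, list(samples)].to_numpy(dtype=float)

    def equals(self, other: "MatchedMatrix") -> bool:
        if list(self.amplitudes.columns) != list(other.amplitudes.columns):
            return False
        if not self.peptides.equals(other.peptides):
            return False
        a, b = self.amplitudes.to_numpy(), other.amplitudes.to_numpy()
        return bool(np.array_equal(np.isnan(a), np.isnan(b))) and bool(
            np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)])
        )


def write_matched_matrix(matrix: MatchedMatrix, path) -> None:
    """Write a matched matrix as one TSV (deterministic row/column order)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        cols = ["master_id", "mass_da", "migration_min", *matrix.sample_ids]
        fh.write("\t".join(cols) + "\n")
        amp = matrix.amplitudes.to_numpy(dtype=float)
        for i, mid in enumerate(matrix.master_ids):
            mass = matrix.peptides["mass_da"].iloc[i]
            mig = matrix.peptides["migration_min"].iloc[i]
            cells = [MISSING if math.isnan(v) else _fmt(v) for v in amp[i]]
            fh.write(f"{mid}\t{round(float(mass), MASS_DECIMALS)}\t"
                     f"{round(float(mig), TIME_DECIMALS)}\t" + "\t".join(cells) + "\n")


def read_matched_matrix(path) -> MatchedMatrix:
    """Read a matched matrix written by :func:`write_matched_matrix`."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    if header[:3] != ["master_id", "mass_da", "migration_min"]:
        raise FormatError(
            f"{path}: header must start with master_id, mass_da, migration_min"
        )
    sample_ids = header[3:]
    ids: list[int] = []
    masses: list[float] = []
    times: list[float] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        row = line.split("\t")
        if len(row) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        ids.append(int(row[0]))
        masses.append(float(row[1]))
        times.append(float(row[2]))
        rows.append([math.nan if c == MISSING else float(c) for c in row[3:]])
    peptides = pd.DataFrame(
        {"mass_da": masses, "migration_min": times},
        index=pd.Index(ids, name="master_id"),
    )
    amplitudes = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(ids), len(sample_ids)),
        index=peptides.index,
        columns=sample_ids,
    )
    return MatchedMatrix(peptides=peptides, amplitudes=amplitudes)
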