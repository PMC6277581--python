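"""FMR1 CGG-repeat genotype semantics and cohort handling.

The FMR1 5'-UTR CGG repeat is classified into four clinical categories by
repeat count: normal (NL, 5-44), intermediate / gray zone (IM_GZ, 45-54),
premutation (PM, 55-199) and full mutation (FM, >= 200).  This module
provides the allele/genotype containers used throughout the package, the
pure category function, and readers/writers for the plain-CSV cohort table
format.  A 151-sample reference cohort of previously genotyped dried blood
spot samples (intellectual disability / autism spectrum referrals, 75 male
and 76 female) ships with the package and drives the end-to-end tests.

Genotype encoding conventions
-----------------------------
* Alleles are ";"-joined integer repeat counts in the ``alleles`` column.
* A token ``a-b`` denotes an expansion smear spanning repeats ``a`` to
  ``b`` (unresolvable on CE); it is represented by its lower bound.
* Females list two primary alleles; any further tokens are treated as
  somatic mosaic components (additional expanded species co-occurring at
  sub-stoichiometric fraction in the same individual).
* A male record listing more than one allele is biologically inconsistent
  with a single X chromosome.  The record is retained with a
  ``sex_allele_mismatch`` flag and only the first listed allele is treated
  as the amplifiable species; the raw string is preserved verbatim.
"""

from __future__ import annotations

import enum
import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "Allele",
    "Genotype",
    "RepeatCategory",
    "CohortRecord",
    "CohortTable",
    "CohortValidationError",
    "category_of",
    "max_allele",
    "load_cohort",
    "write_cohort",
    "load_reference_cohort",
    "parse_allele_field",
    "MAX_REPEATS",
]

#: sanity cap on a single-allele repeat count
MAX_REPEATS = 2000

#: default fraction of total template mass attributed to the mosaic
#: compartment of a mosaic genotype (split equally among components)
DEFAULT_MOSAIC_FRACTION_TOTAL = 0.4


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the format or sex/allele rules."""


class RepeatCategory(enum.IntEnum):
    """Clinical CGG-repeat category, ordered by expansion severity."""

    NL = 0
    IM_GZ = 1
    PM = 2
    FM = 3

    def __str__(self) -> str:  # report-friendly
        return self.name


# inclusive (lower, upper) bounds per category; FM is open-ended
CATEGORY_BOUNDS = {
    RepeatCategory.NL: (5, 44),
    RepeatCategory.IM_GZ: (45, 54),
    RepeatCategory.PM: (55, 199),
    RepeatCategory.FM: (200, None),
}


def category_of(repeats: int) -> RepeatCategory:
    """Map a CGG repeat count to its clinical category.

    Counts of 1-4 fall below the conventional normal-range floor of 5;
    the screen only distinguishes expanded from non-expanded, so they are
    mapped to NL (a short allele melts even earlier than a normal one).

    Raises
    ------
    ValueError
        If ``repeats`` is not a positive integer.
    """
    r = int(repeats)
    if r != repeats or r < 1:
        raise ValueError(f"repeat count must be a positive integer, got {repeats!r}")
    if r >= 200:
        return RepeatCategory.FM
    if r >= 55:
        return RepeatCategory.PM
    if r >= 45:
        return RepeatCategory.IM_GZ
    return RepeatCategory.NL


@dataclass(frozen=True)
class Allele:
    """One CGG-repeat species.

    ``smear_upper`` records the upper bound of an unresolved expansion
    smear (``a-b`` notation); ``repeats`` is then the lower bound.
    """

    repeats: int
    smear_upper: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.repeats <= MAX_REPEATS):
            raise ValueError(f"repeats out of range [1, {MAX_REPEATS}]: {self.repeats}")
        if self.smear_upper is not None and self.smear_upper < self.repeats:
            raise ValueError("smear upper bound below lower bound")

    @property
    def category(self) -> RepeatCategory:
        return category_of(self.repeats)


@dataclass(frozen=True)
class Genotype:
    """Sex plus primary alleles and optional mosaic components.

    ``mosaic_components`` holds ``(Allele, fraction)`` pairs for additional
    repeat species beyond the primary allele(s); fractions must sum to <= 1.
    ``flags`` carries validation annotations (e.g. ``sex_allele_mismatch``)
    and ``raw_alleles`` the verbatim allele string it was parsed from.
    """

    sample_id: str
    sex: str  # "M" or "F"
    alleles: tuple[Allele, ...]
    mosaic_components: tuple[tuple[Allele, float], ...] = ()
    flags: tuple[str, ...] = ()
    raw_alleles: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.alleles:
            raise ValueError(f"{self.sample_id}: genotype has no alleles")
        n_expected = 1 if self.sex == "M" else 2
        if len(self.alleles) != n_expected and "sex_allele_mismatch" not in self.flags:
            raise ValueError(
                f"{self.sample_id}: {self.sex} genotype must carry {n_expected} "
                f"primary allele(s), got {len(self.alleles)}"
            )
        frac = sum(f for _, f in self.mosaic_components)
        if frac > 1.0 + 1e-9:
            raise ValueError(f"{self.sample_id}: mosaic fractions sum to {frac} > 1")

    @property
    def is_mosaic(self) -> bool:
        return bool(self.mosaic_components)

    def all_components(self) -> list[tuple[Allele, float]]:
        """Primary alleles and mosaic components with their mass fractions.

        Primary alleles share the non-mosaic fraction equally.
        """
        mosaic_total = sum(f for _, f in self.mosaic_components)
        primary_w = (1.0 - mosaic_total) / len(self.alleles)
        out = [(a, primary_w) for a in self.alleles]
        out.extend(self.mosaic_components)
        return out


def max_allele(genotype: Genotype) -> int:
    """Largest repeat count across primary alleles and mosaic components.

    The melt screen responds to the largest repeat species present, so
    classification keys off this value.
    """
    if not genotype.alleles:
        raise ValueError("genotype has no alleles")
    counts = [a.repeats for a in genotype.alleles]
    counts += [a.repeats for a, _ in genotype.mosaic_components]
    return max(counts)


@dataclass(frozen=True)
class CohortRecord:
    sample_id: str
    sex: str
    genotype: Genotype
    known_status: RepeatCategory


@dataclass
class CohortTable:
    """Ordered collection of cohort records with unique sample ids."""

    records: list[CohortRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate sample_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> CohortRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "CohortTable":
        wanted = set(sample_ids)
        return CohortTable([r for r in self.records if r.sample_id in wanted])


_ALLELE_TOKEN = re.compile(r"^(\d+)(?:-(\d+))?$")


def parse_allele_field(
    text: str, sex: str, sample_id: str = "?"
) -> tuple[tuple[Allele, ...], tuple[tuple[Allele, float], ...], tuple[str, ...]]:
    """Parse a ";"-joined allele field into primaries, mosaics and flags."""
    tokens = [t.strip() for t in str(text).split(";") if t.strip()]
    if not tokens:
        raise CohortValidationError(f"{sample_id}: empty allele field")
    alleles: list[Allele] = []
    for tok in tokens:
        m = _ALLELE_TOKEN.match(tok)
        if not m:
            raise CohortValidationError(f"{sample_id}: unparseable allele token {tok!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else None
        alleles.append(Allele(lo, smear_upper=hi))

    flags: list[str] = []
    if sex == "M":
        primary, extra = alleles[:1], alleles[1:]
        if extra:
            # one X chromosome: >1 allele is an annotation inconsistency.
            # Keep the record, flag it, treat the first allele as real.
            flags.append("sex_allele_mismatch")
        mosaic: list[tuple[Allele, float]] = []
    else:
        if len(alleles) < 2:
            flags.append("sex_allele_mismatch")
            primary, rest = alleles, []
        else:
            primary, rest = alleles[:2], alleles[2:]
        if rest:
            per = DEFAULT_MOSAIC_FRACTION_TOTAL / len(rest)
            mosaic = [(a, per) for a in rest]
        else:
            mosaic = []
    below_floor = [a.repeats for a in primary if a.repeats < 5]
    if below_floor:
        flags.append("below_normal_floor")
    return tuple(primary), tuple(mosaic), tuple(flags)


def _records_from_dataframe(df, source: str) -> list[CohortRecord]:
    import pandas as pd  # local to keep module import light

    required = {"sample_id", "sex", "alleles", "status"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"{source}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        sid = str(row.sample_id)
        sex = {"M": "M", "MALE": "M", "F": "F", "FEMALE": "F"}.get(
            str(row.sex).strip().upper()
        )
        if sex is None:
            raise CohortValidationError(f"{source} line {line}: bad sex {row.sex!r}")
        try:
            status = RepeatCategory[str(row.status).strip()]
        except KeyError:
            raise CohortValidationError(
                f"{source} line {line}: bad status {row.status!r}"
            ) from None
        try:
            primary, mosaic, flags = parse_allele_field(row.alleles, sex, sid)
        except CohortValidationError as e:
            raise CohortValidationError(f"{source} line {line}: {e}") from None
        gt = Genotype(
            sample_id=sid,
            sex=sex,
            alleles=primary,
            mosaic_components=mosaic,
            flags=flags,
            raw_alleles=str(row.alleles),
        )
        records.append(CohortRecord(sid, sex, gt, status))
    return records


def load_cohort(path: str | Path) -> CohortTable:
    """Read a cohort table from CSV/TSV.

    Expected columns: ``sample_id``, ``sex`` (M/F), ``alleles``
    (";"-joined repeat counts, ``a-b`` for smears), ``status`` (NL/PM/FM).
    Malformed rows raise :class:`CohortValidationError` naming the line;
    sex/allele-count mismatches are flagged on the record, not rejected.
    """
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return CohortTable(_records_from_dataframe(df, str(path)))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table back to CSV, preserving verbatim allele strings."""
    import pandas as pd

    rows = []
    for r in cohort:
        alleles = r.genotype.raw_alleles
        if alleles is None:
            toks = [
                str(a.repeats) if a.smear_upper is None else f"{a.repeats}-{a.smear_upper}"
                for a in r.genotype.alleles
            ] + [str(a.repeats) for a, _ in r.genotype.mosaic_components]
            alleles = ";".join(toks)
        rows.append(
            {
                "sample_id": r.sample_id,
                "sex": r.sex,
                "alleles": alleles,
                "status": r.known_status.name,
            }
        )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(rows, columns=["sample_id", "sex", "alleles", "status"]).to_csv(
        path, sep=sep, index=False
    )


def reference_cohort_path() -> Path:
    """Path of the packaged 151-sample reference cohort CSV."""
    return Path(importlib.resources.files("fxscreen").joinpath("data/table1_cohort.csv"))


def load_reference_cohort() -> CohortTable:
    """Load the packaged 151-sample dried-blood-spot reference cohort."""
    return load_cohort(reference_cohort_path())
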