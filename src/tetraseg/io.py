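"""CSV input/output for observed counts and fraction/ratio parsing helpers.

The on-disk schema is a four-column CSV::

    assay,category_a,category_b,group_label
    seed_set,171,507,selfed_4x
    progeny,327,25,selfed_4x

``assay`` is one of ``seed_set``, ``progeny``, ``fg_phenotype``; category_a
is the first-named count of the assay (infertile / resistant / proliferating).
Ratios may be written with an ASCII ``:``; the Unicode ratio sign ``∶`` is
accepted on input.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

from .expectations import Assay
from .gametes import as_fraction
from .inference import ObservedCounts

__all__ = [
    "CSV_COLUMNS",
    "parse_fraction",
    "parse_ratio",
    "read_observed_csv",
    "write_observed_csv",
    "reference_observed_counts",
]

CSV_COLUMNS = ("assay", "category_a", "category_b", "group_label")

#: Unicode ratio sign, normalised to ":" on input.
RATIO_SIGN = "∶"


def parse_fraction(text: str) -> Fraction:
    """Parse ``"1/6"``, ``"0.1"`` or ``"0"`` to an exact Fraction."""
    text = text.strip()
    try:
        if "/" in text:
            return Fraction(text)
        return as_fraction(float(text)) if "." in text or "e" in text.lower() else Fraction(text)
    except (ValueError, ZeroDivisionError) as err:
        raise ValueError(f"cannot parse fraction from {text!r}") from err


def parse_ratio(text: str) -> tuple[int, int]:
    """Parse ``"171:507"`` (or with the Unicode ratio sign) to two ints."""
    parts = text.strip().replace(RATIO_SIGN, ":").split(":")
    if len(parts) != 2:
        raise ValueError(f"expected two ':'-separated counts, got {text!r}")
    try:
        return int(parts[0]), int(parts[1])
    except ValueError as err:
        raise ValueError(f"non-integer count in ratio {text!r}") from err


def read_observed_csv(source: str | Path | TextIO) -> list[ObservedCounts]:
    """Read observed counts; malformed rows raise with their line number."""
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return read_observed_csv(fh)
    reader = csv.DictReader(source)
    missing = set(CSV_COLUMNS[:3]) - set(reader.fieldnames or ())
    if missing:
        raise ValueError(f"missing CSV columns: {sorted(missing)}")
    out = []
    for row in reader:
        try:
            out.append(
                ObservedCounts(
                    assay=Assay(row["assay"].strip()),
                    category_a=int(row["category_a"]),
                    category_b=int(row["category_b"]),
                    label=(row.get("group_label") or "").strip(),
                )
            )
        except (KeyError, ValueError, TypeError) as err:
            raise ValueError(f"malformed CSV row at line {reader.line_num}: {err}") from err
    if not out:
        raise ValueError("no observed-count rows found")
    return out


def write_observed_csv(
    counts: Iterable[ObservedCounts], dest: str | Path | TextIO
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="") as fh:
            write_observed_csv(counts, fh)
            return
    writer = csv.writer(dest)
    writer.writerow(CSV_COLUMNS)
    for o in counts:
        writer.writerow([o.assay.value, o.category_a, o.category_b, o.label])


def reference_observed_counts() -> list[ObservedCounts]:
    """The bundled observed counts of the original rbr-3 tetraploid selfing
    experiments (seed-set and progeny assays per phenotypic group)."""
    ref = resources.files("tetraseg.data").joinpath("reference_counts.csv")
    with ref.open(newline="") as fh:
        return read_observed_csv(fh)
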