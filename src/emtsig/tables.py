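"""Readers and writers for the pipeline's tabular inputs and outputs.

All files are tab-separated UTF-8 with a header row. p-values printed as
upper bounds (``<1e-12``) are parsed to the bound's numeric value with a
``bound`` flag so that round-tripping preserves the distinction between
"p equals 1e-12" and "p is below 1e-12".

Two fixtures ship with the package: the diagnostic table of genes
deregulated in breast tumors versus normal tissue (117 genes, up/down) and
the prognostic table of genes whose optimal-cutpoint split is coherently
significant across DMFS, OS and RFS (worse/better panels). Load them with
:func:`load_diagnostic_fixture` and :func:`load_prognostic_fixture`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, IntegrityError

__all__ = [
    "DiagnosticTableRow",
    "PrognosticTableRow",
    "SignatureEntry",
    "parse_p",
    "format_p",
    "read_diagnostic_table",
    "read_prognostic_table",
    "load_diagnostic_fixture",
    "load_prognostic_fixture",
    "write_signature_report",
    "read_signature_report",
]


@dataclass(frozen=True)
class DiagnosticTableRow:
    """One gene of the tumor-vs-normal differential table.

    ``p_bound`` marks p-values printed as upper bounds; ``p_value`` then
    holds the bound itself.
    """

    gene: str
    direction: str  # "up" | "down"
    p_value: float
    p_bound: bool = False


@dataclass(frozen=True)
class PrognosticTableRow:
    """One gene of the three-endpoint survival table.

    ``direction`` is a single label per gene ("worse" or "better": the
    prognosis associated with high expression). Bound flags parallel the
    three endpoint p-values.
    """

    gene: str
    direction: str  # "worse" | "better"
    p_dmfs: float
    p_os: float
    p_rfs: float
    bound_dmfs: bool = False
    bound_os: bool = False
    bound_rfs: bool = False


@dataclass(frozen=True)
class SignatureEntry:
    """A gene present in both the diagnostic and prognostic tables."""

    gene: str
    diagnostic_direction: str  # "up" | "down"
    prognostic_direction: str  # "worse" | "better"
    concordant: bool
    klass: str  # "up_worse" | "down_better" | "discordant"


def parse_p(text: str) -> tuple[float, bool]:
    """Parse a p-value cell; a ``<`` prefix marks an upper bound."""
    text = text.strip()
    bound = text.startswith("<")
    if bound:
        text = text[1:].strip()
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable p-value {text!r}") from exc
    if not 0.0 < value <= 1.0:
        raise FormatError(f"p-value {value} outside (0, 1]")
    return value, bound


def format_p(value: float, bound: bool) -> str:
    return f"<{value:g}" if bound else f"{value:g}"


def _read_rows(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        return list(reader)


def _check_unique_genes(genes: Iterable[str], path: str | Path) -> None:
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise IntegrityError(f"{path}: duplicate gene symbol {g!r}")
        seen.add(g)


def read_diagnostic_table(path: str | Path) -> list[DiagnosticTableRow]:
    """Read a TSV of per-gene differential calls (columns gene, direction,
    p_value)."""
    rows = []
    for rec in _read_rows(path, ("gene", "direction", "p_value")):
        gene = (rec["gene"] or "").strip()
        if not gene:
            raise FormatError(f"{path}: empty gene symbol")
        direction = (rec["direction"] or "").strip()
        if direction not in ("up", "down"):
            raise FormatError(f"{path}: bad direction {direction!r} for {gene}")
        p, bound = parse_p(rec["p_value"] or "")
        rows.append(DiagnosticTableRow(gene, direction, p, bound))
    _check_unique_genes((r.gene for r in rows), path)
    return rows


def read_prognostic_table(path: str | Path) -> list[PrognosticTableRow]:
    """Read a TSV of per-gene three-endpoint prognostic calls (columns
    gene, direction, p_dmfs, p_os, p_rfs)."""
    rows = []
    for rec in _read_rows(path, ("gene", "direction", "p_dmfs", "p_os", "p_rfs")):
        gene = (rec["gene"] or "").strip()
        if not gene:
            raise FormatError(f"{path}: empty gene symbol")
        direction = (rec["direction"] or "").strip()
        if direction not in ("worse", "better"):
            raise FormatError(f"{path}: bad direction {direction!r} for {gene}")
        ps = {}
        bounds = {}
        for ep in ("dmfs", "os", "rfs"):
            cell = rec[f"p_{ep}"]
            if cell is None or not cell.strip():
                raise FormatError(f"{path}: missing p_{ep} for {gene}")
            ps[ep], bounds[ep] = parse_p(cell)
        rows.append(
            PrognosticTableRow(
                gene,
                direction,
                ps["dmfs"],
                ps["os"],
                ps["rfs"],
                bounds["dmfs"],
                bounds["os"],
                bounds["rfs"],
            )
        )
    _check_unique_genes((r.gene for r in rows), path)
    return rows


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("emtsig").joinpath("data", name)))


def load_diagnostic_fixture() -> list[DiagnosticTableRow]:
    """The packaged diagnostic table: 117 genes, 57 up and 60 down."""
    return read_diagnostic_table(_fixture_path("table1_diagnostic.tsv"))


def load_prognostic_fixture() -> list[PrognosticTableRow]:
    """The packaged prognostic table: 33 worse-panel rows and 28 better.

    The source publication's text counts 32 worse-prognosis genes while its
    table prints 33 rows (CKMT1A and CKMT1B appear as separate rows with
    identical statistics); the fixture reproduces the table as printed.
    """
    return read_prognostic_table(_fixture_path("table2_prognostic.tsv"))


_SIGNATURE_COLUMNS = (
    "gene",
    "diagnostic_direction",
    "prognostic_direction",
    "concordant",
    "class",
)


def write_signature_report(entries: Sequence[SignatureEntry], path: str | Path) -> None:
    """Write signature entries as TSV, sorted by gene symbol."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SIGNATURE_COLUMNS)
        for e in sorted(entries, key=lambda e: e.gene):
            writer.writerow(
                [
                    e.gene,
                    e.diagnostic_direction,
                    e.prognostic_direction,
                    "true" if e.concordant else "false",
                    e.klass,
                ]
            )


def read_signature_report(path: str | Path) -> list[SignatureEntry]:
    entries = []
    for rec in _read_rows(path, _SIGNATURE_COLUMNS):
        entries.append(
            SignatureEntry(
                gene=rec["gene"].strip(),
                diagnostic_direction=rec["diagnostic_direction"].strip(),
                prognostic_direction=rec["prognostic_direction"].strip(),
                concordant=rec["concordant"].strip() == "true",
                klass=rec["class"].strip(),
            )
        )
    _check_unique_genes((e.gene for e in entries), path)
    return entries
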