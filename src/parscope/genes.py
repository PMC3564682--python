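"""Classify gene best-match locations relative to a pseudoautosomal interval.

Given, for each gene, the location of its closest genomic match (or the
absence of one), genes fall into four categories with respect to a PAR
defined on the X chromosome:

* ``NO_MATCH`` — no significant match anywhere in the genome;
* ``WITHIN_PAR`` — matched on the X proximal to the boundary interval, or
  explicitly flagged as hitting PAR sequence;
* ``X_OUTSIDE_PAR`` — matched on the X distal to the boundary;
* ``AUTOSOMAL`` — closest match on any other chromosome.

Records listing several chromosomes classify by the first listed (the
closest match), with the full list retained. A curated example table of
human PAR1 genes and their pig best-match locations ships with the package
(``parscope.genes.bundled_gene_table``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .pab import PABCall

__all__ = [
    "GeneMatchRecord",
    "GeneCategory",
    "ClassifiedGene",
    "load_gene_matches",
    "bundled_gene_table",
    "classify_gene",
    "classify_genes",
    "summarize_classification",
]

PAR_REGION_FLAG = "par_region"


class GeneCategory(Enum):
    NO_MATCH = "NO_MATCH"
    AUTOSOMAL = "AUTOSOMAL"
    X_OUTSIDE_PAR = "X_OUTSIDE_PAR"
    WITHIN_PAR = "WITHIN_PAR"


@dataclass(frozen=True)
class GeneMatchRecord:
    """One gene's best genomic match: chromosome list + optional position.

    ``chroms`` is empty for no-match records. ``position`` (bp) may be
    absent — some matches report a chromosome only. ``flags`` carries
    curation notes; the ``par_region`` flag marks matches that hit PAR
    sequence directly even without a positional coordinate.
    """

    gene_id: str
    symbol: str
    chroms: tuple[str, ...] = ()
    position: Optional[int] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.chroms and self.position is not None:
            raise ValueError(
                f"{self.gene_id}: a position without a chromosome is malformed"
            )


@dataclass(frozen=True)
class ClassifiedGene:
    gene_id: str
    symbol: str
    category: GeneCategory


class GeneTableError(ValueError):
    """A malformed row in a gene match table."""


def _parse_flags(raw) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return ()
    return tuple(s.strip() for s in str(raw).split(",") if s.strip())


def load_gene_matches(source: Union[str, Path]) -> list[GeneMatchRecord]:
    """Read a gene match TSV: gene_id, symbol, chrom (or NO_MATCH), position, flags.

    ``chrom`` may list several chromosomes separated by ';' (first = closest
    match). ``position`` is bp or empty. Malformed rows are rejected with
    their row identity.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    required = ["gene_id", "symbol", "chrom", "position", "flags"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GeneTableError(f"gene table missing columns {missing}")
    records = []
    for r in df.itertuples():
        gid = str(r.gene_id)
        chrom_field = "" if pd.isna(r.chrom) else str(r.chrom).strip()
        try:
            if chrom_field.upper() in ("", "NO_MATCH"):
                chroms: tuple[str, ...] = ()
                pos = None
                if not pd.isna(r.position) and str(r.position).strip():
                    raise ValueError("position given for a NO_MATCH row")
            else:
                chroms = tuple(c.strip() for c in chrom_field.split(";") if c.strip())
                pos_field = "" if pd.isna(r.position) else str(r.position).strip()
                pos = int(float(pos_field)) if pos_field else None
            records.append(
                GeneMatchRecord(
                    gene_id=gid,
                    symbol=str(r.symbol),
                    chroms=chroms,
                    position=pos,
                    flags=_parse_flags(r.flags),
                )
            )
        except ValueError as exc:
            raise GeneTableError(f"gene {gid!r} (row {r.Index}): {exc}") from None
    return records


def bundled_gene_table() -> list[GeneMatchRecord]:
    """The packaged 16-gene human-PAR1 vs pig best-match example table."""
    ref = resources.files("parscope.data").joinpath("human_par1_pig_matches.tsv")
    with resources.as_file(ref) as p:
        return load_gene_matches(p)


def classify_gene(
    record: GeneMatchRecord,
    par: Union[PABCall, tuple[int, int]],
    x_chrom: str = "X",
) -> ClassifiedGene:
    """Place one gene's best match relative to the PAR.

    ``par`` is a boundary call or an explicit (interval_start, interval_end)
    tuple in bp. An X match counts as within the PAR if its position is
    proximal to the boundary interval's start, or if the record carries the
    ``par_region`` flag (a match into PAR sequence without a coordinate).
    """
    if isinstance(par, PABCall):
        interval_start = par.interval_start
    else:
        interval_start = par[0]

    if not record.chroms:
        cat = GeneCategory.NO_MATCH
    else:
        first = record.chroms[0]
        is_x = first.upper().lstrip("SSC") == x_chrom.upper() or first.upper() == x_chrom.upper()
        if PAR_REGION_FLAG in record.flags:
            cat = GeneCategory.WITHIN_PAR
        elif is_x:
            if record.position is not None and record.position < interval_start:
                cat = GeneCategory.WITHIN_PAR
            else:
                cat = GeneCategory.X_OUTSIDE_PAR
        else:
            cat = GeneCategory.AUTOSOMAL
    return ClassifiedGene(record.gene_id, record.symbol, cat)


def classify_genes(
    records: Sequence[GeneMatchRecord],
    par: Union[PABCall, tuple[int, int]],
    x_chrom: str = "X",
) -> list[ClassifiedGene]:
    return [classify_gene(r, par, x_chrom=x_chrom) for r in records]


def summarize_classification(
    classified: Sequence[ClassifiedGene],
) -> dict[str, int]:
    """Category counts plus the total; counts always sum to the total."""
    counts = {cat.value: 0 for cat in GeneCategory}
    for g in classified:
        counts[g.category.value] += 1
    counts["total"] = len(classified)
    return counts


def classification_frame(classified: Sequence[ClassifiedGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in classified],
            "symbol": [g.symbol for g in classified],
            "category": [g.category.value for g in classified],
        }
    )
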