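"""Schema-checked delimited-table I/O shared by all stages.

All tables are tab-separated with a header row.  ``validate_and_load``
checks the column set against a named schema, coerces numeric columns, and
reports malformed rows with line numbers.  FASTA goes through Biopython.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: schema name -> (required columns, numeric columns). Lanthanide columns
#: (l1..lL) are matched by prefix and always numeric.
SCHEMAS = {
    "beads": (
        ["bead_id", "intensity", "condition", "replicate_id", "sample_id"],
        ["intensity", "condition"],
    ),
    "codes": (["code_id"], []),
    "library": (["peptide_id", "code_id", "sequence"], []),
    "summaries": (
        ["code_id", "condition", "replicate_id", "n_beads", "central_intensity", "dispersion"],
        ["condition", "n_beads", "central_intensity", "dispersion"],
    ),
    "dephos_results": (
        ["peptide_id", "enzyme", "score_mean", "score_sd"],
        ["score_mean", "score_sd"],
    ),
    "affinity_results": (
        ["peptide_id", "kd_final", "kd_spread"],
        ["kd_final", "kd_spread"],
    ),
    "sites": (
        ["site_id", "protein_id", "position", "acceptor", "window"],
        ["position"],
    ),
    "interactors": (
        ["protein_id", "bait", "log2_enrichment", "p_value", "interactor"],
        ["log2_enrichment", "p_value"],
    ),
    "motif_matches": (
        ["protein_id", "start", "end", "variant", "matched_text"],
        ["start", "end"],
    ),
}


def _lanthanide_columns(columns) -> list:
    return sorted(
        (c for c in columns if c.startswith("l") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )


def validate_and_load(path, schema: str) -> pd.DataFrame:
    """Load a TSV and validate it against a named schema.

    Raises :class:`SchemaError` naming missing columns, or pointing at the
    first malformed (non-numeric) cell with its 1-based data line number.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    required, numeric = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing} for schema {schema!r}")
    numeric = list(numeric) + _lanthanide_columns(df.columns)
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 1-based
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = coerced
    logger.info("%s: loaded %d rows x %d columns (schema %s)", path.name, *df.shape, schema)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_fasta(path) -> dict:
    """FASTA -> {record id: sequence string}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
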