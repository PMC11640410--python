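"""Readers and writers for the pipeline's plain-text exchange formats.

All formats are tab-separated text: interaction tables (miRNA -> gene),
GMT gene-set collections, STRING-style protein-interaction edge lists, and
survival tables.  Expression matrices live on :class:`~mirmeta.studies.ExpressionStudy`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

INTERACTION_COLUMNS = ["mirna_id", "gene_symbol", "source_db", "validated"]
EDGE_COLUMNS = ["node_a", "node_b", "score"]
SURVIVAL_COLUMNS = ["sample_id", "time", "event", "expression"]


# ---------------------------------------------------------------------------
# miRNA -> gene interaction tables
# ---------------------------------------------------------------------------
def read_interactions(path) -> pd.DataFrame:
    """Read a validated-interaction table (multiMiR-export-like TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"validated": int})
    missing = set(INTERACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    _check_interactions(df)
    return df[INTERACTION_COLUMNS]


def write_interactions(df: pd.DataFrame, path) -> None:
    _check_interactions(df)
    df[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)


def _check_interactions(df: pd.DataFrame) -> None:
    if df["mirna_id"].eq("").any() or df["gene_symbol"].eq("").any():
        raise ValueError("interaction ids must be non-empty")
    dup = df.duplicated(subset=["mirna_id", "gene_symbol", "source_db"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicated (mirna, gene, source) interaction rows"
        )


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------
def read_gmt(path, category: str = "pathway") -> list[tuple[str, str, str, frozenset]]:
    """Parse a GMT file into (term_id, name, category, gene set) tuples.

    Standard GMT: one term per line, ``name<TAB>description<TAB>gene1<TAB>...``.
    The first field is used as the term id and the second as its display name.
    """
    terms = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
        term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise ValueError(f"{path}: line {lineno}: empty gene set '{term_id}'")
        terms.append((term_id, name, category, frozenset(genes)))
    return terms


def write_gmt(terms, path) -> None:
    lines = []
    for term_id, name, _category, genes in terms:
        lines.append("\t".join([term_id, name, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------
def read_edge_list(path) -> pd.DataFrame:
    """Read ``node_a<TAB>node_b<TAB>score`` rows; errors carry the line number."""
    rows = []
    lines = Path(path).read_text().splitlines()
    start = 0
    if lines and lines[0].split("\t")[:2] == ["node_a", "node_b"]:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 fields")
        try:
            score = float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: bad score {parts[2]!r}") from exc
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"{path}: line {lineno}: score {score} outside [0, 1]")
        rows.append((parts[0], parts[1], score))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def write_edge_list(df: pd.DataFrame, path) -> None:
    df[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------
def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    _check_survival(df)
    return df[SURVIVAL_COLUMNS]


def write_survival(df: pd.DataFrame, path) -> None:
    _check_survival(df)
    df[SURVIVAL_COLUMNS].to_csv(path, sep="\t", index=False)


def _check_survival(df: pd.DataFrame) -> None:
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in survival table")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
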