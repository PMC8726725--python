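"""Genus-level microbiome preprocessing.

Turns an OTU/taxon count table into the prevalence-filtered, genus-level
relative-abundance matrix used as the microbiome modality of the linked
factorization.  The canonical order of operations is: aggregate counts to
genus, drop genera detected (count > 0) in fewer than 30% of samples, then
normalize each sample to proportions.  Normalizing before filtering (so
retained proportions are those computed on the full table and rows no
longer sum to 1) is available behind ``order="normalize-first"``.

Supported formats: a TSV dialect with taxa as rows (first column taxon id,
last column a semicolon-ranked taxonomy lineage) and BIOM v1 JSON.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError, ParseError

__all__ = [
    "AbundanceTable",
    "CompositionTable",
    "read_table",
    "write_table",
    "aggregate_to_genus",
    "prevalence_filter",
    "to_relative_abundance",
    "prepare_microbiome",
    "genus_label",
]

_RANK_RE = re.compile(r"^([a-z])__(.*)$")


@dataclass
class AbundanceTable:
    """Sample x taxon count matrix with per-taxon taxonomy lineages."""

    counts: np.ndarray            # (n_samples, n_taxa) non-negative integers
    taxonomy: list[str]
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DimensionError("counts must be a 2-D sample x taxon matrix")
        n_samples, n_taxa = self.counts.shape
        if len(self.sample_ids) != n_samples:
            raise DimensionError("sample_ids length does not match counts rows")
        if len(self.taxon_ids) != n_taxa:
            raise DimensionError("taxon_ids length does not match counts columns")
        if len(self.taxonomy) != n_taxa:
            raise DimensionError("taxonomy length must equal the taxon count")
        if len(set(self.sample_ids)) != n_samples:
            raise ParameterError("sample ids must be unique")
        if len(set(self.taxon_ids)) != n_taxa:
            raise ParameterError("taxon ids must be unique")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ParseError("counts must be numeric")
        if np.any(self.counts < 0):
            s, t = np.argwhere(self.counts < 0)[0]
            raise ParseError(
                f"negative count at sample {self.sample_ids[s]!r}, "
                f"taxon {self.taxon_ids[t]!r}"
            )
        if not np.allclose(self.counts, np.round(self.counts)):
            s, t = np.argwhere(~np.isclose(self.counts, np.round(self.counts)))[0]
            raise ParseError(
                f"non-integer count at sample {self.sample_ids[s]!r}, "
                f"taxon {self.taxon_ids[t]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Taxa-as-rows frame in the package's TSV dialect."""
        df = pd.DataFrame(
            self.counts.T, index=pd.Index(self.taxon_ids, name="taxon_id"),
            columns=self.sample_ids,
        )
        df["taxonomy"] = self.taxonomy
        return df


@dataclass
class CompositionTable:
    """Sample x genus relative-abundance matrix.

    ``renormalized=False`` marks tables whose proportions were computed
    before column filtering, so rows may sum to less than 1.
    """

    relabund: np.ndarray          # (n_samples, n_genera)
    genus_ids: list[str]
    sample_ids: list[str]
    renormalized: bool = field(default=True)

    def __post_init__(self) -> None:
        self.relabund = np.asarray(self.relabund, dtype=float)
        if self.relabund.ndim != 2:
            raise DimensionError("relabund must be 2-D")
        n_samples, n_genera = self.relabund.shape
        if len(self.sample_ids) != n_samples or len(self.genus_ids) != n_genera:
            raise DimensionError("id lists do not match relabund shape")
        if np.any(self.relabund < 0) or np.any(self.relabund > 1):
            raise ParameterError("relative abundances must lie in [0, 1]")
        if self.renormalized:
            sums = self.relabund.sum(axis=1)
            bad = np.flatnonzero(~np.isclose(sums, 1.0, atol=1e-9))
            if bad.size:
                raise ParameterError(
                    f"rows must sum to 1; first offender sample "
                    f"{self.sample_ids[bad[0]]!r} sums to {sums[bad[0]]!r}"
                )


def genus_label(lineage: str) -> str:
    """Genus name from a semicolon-ranked lineage string.

    Taxa without a named genus are pooled under their lowest named rank,
    prefixed ``unclassified_``.
    """
    tokens = [t.strip() for t in lineage.split(";") if t.strip()]
    named = []
    for tok in tokens:
        m = _RANK_RE.match(tok)
        rank, name = (m.group(1), m.group(2)) if m else (None, tok)
        if name:
            named.append((rank, name))
            if rank == "g":
                return name
    if named:
        return f"unclassified_{named[-1][1]}"
    return "unclassified_root"


def _read_tsv(path: Path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if "taxonomy" not in df.columns:
        raise ParseError(f"{path}: TSV table must carry a final 'taxonomy' column")
    taxonomy = df["taxonomy"].fillna("").tolist()
    data = df.drop(columns=["taxonomy"])
    counts = np.empty((data.shape[0], data.shape[1]), dtype=float)
    for j, col in enumerate(data.columns):
        try:
            counts[:, j] = pd.to_numeric(data[col], errors="raise")
        except (ValueError, TypeError):
            bad = data[col][pd.to_numeric(data[col], errors="coerce").isna()].index[0]
            raise ParseError(
                f"{path}: non-numeric count at taxon {bad!r}, sample {col!r}"
            ) from None
    return AbundanceTable(
        counts=counts.T,
        taxonomy=taxonomy,
        sample_ids=list(data.columns),
        taxon_ids=[str(i) for i in data.index],
    )


def _read_biom(path: Path) -> AbundanceTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        n_obs, n_samples = doc["shape"]
        rows = doc["rows"]
        cols = doc["columns"]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except KeyError as e:  # pragma: no cover - malformed input
        raise ParseError(f"{path}: missing BIOM field {e}") from None
    counts = np.zeros((n_obs, n_samples), dtype=float)
    if matrix_type == "dense":
        counts[:] = np.asarray(data, dtype=float)
    elif matrix_type == "sparse":
        for i, j, v in data:
            counts[int(i), int(j)] = v
    else:
        raise ParseError(f"{path}: unknown matrix_type {matrix_type!r}")
    taxonomy = []
    for r in rows:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy", "")
        taxonomy.append(";".join(tax) if isinstance(tax, list) else str(tax))
    return AbundanceTable(
        counts=counts.T,
        taxonomy=taxonomy,
        sample_ids=[c["id"] for c in cols],
        taxon_ids=[r["id"] for r in rows],
    )


def read_table(path, format: str = "auto") -> AbundanceTable:
    """Read a count table from TSV or BIOM v1 JSON."""
    path = Path(path)
    if format == "auto":
        format = "biom" if path.suffix.lower() == ".biom" else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ParameterError(f"unknown table format {format!r}")


def write_table(table: AbundanceTable, path, format: str = "auto",
                header_comment: str | None = None) -> None:
    """Write a count table as TSV (taxa as rows) or BIOM v1 JSON."""
    path = Path(path)
    if format == "auto":
        format = "biom" if path.suffix.lower() == ".biom" else "tsv"
    if format == "tsv":
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            table.to_dataframe().to_csv(fh, sep="\t")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "gblica",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [
                {"id": tid, "metadata": {"taxonomy": [t.strip() for t in tax.split(";")]}}
                for tid, tax in zip(table.taxon_ids, table.taxonomy)
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ParameterError(f"unknown table format {format!r}")


def aggregate_to_genus(table: AbundanceTable) -> AbundanceTable:
    """Sum counts over taxa sharing a genus label (first-appearance order)."""
    labels = [genus_label(t) for t in table.taxonomy]
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, lab in enumerate(labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(j)
    counts = np.column_stack(
        [table.counts[:, groups[lab]].sum(axis=1) for lab in order]
    ) if order else np.zeros((table.n_samples, 0), dtype=np.int64)
    taxonomy = []
    for lab in order:
        first = table.taxonomy[groups[lab][0]]
        if lab.startswith("unclassified_"):
            taxonomy.append(first)
        else:
            # truncate the representative lineage after the genus token
            tokens = [t.strip() for t in first.split(";")]
            cut = next(
                (i for i, t in enumerate(tokens) if t == f"g__{lab}"), len(tokens) - 1
            )
            taxonomy.append(";".join(tokens[: cut + 1]))
    return AbundanceTable(
        counts=counts,
        taxonomy=taxonomy,
        sample_ids=list(table.sample_ids),
        taxon_ids=order,
    )


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    # repr() gives the shortest decimal literal, so 0.3 -> 3/10 exactly
    return Fraction(repr(float(x)))


def prevalence_filter(table: AbundanceTable, min_prevalence=Fraction(3, 10)) -> AbundanceTable:
    """Retain taxa present (count > 0) in at least ``min_prevalence`` of samples.

    The "at least" boundary is inclusive and compared in exact rational
    arithmetic, so a taxon sitting exactly on the threshold is retained.
    """
    frac = _as_fraction(min_prevalence)
    if not 0 < frac <= 1:
        raise ParameterError(f"min_prevalence must be in (0, 1], got {min_prevalence}")
    if table.n_taxa == 0 or table.n_samples == 0:
        warnings.warn("prevalence_filter applied to an empty table", stacklevel=2)
        return table
    present = (table.counts > 0).sum(axis=0)
    keep = [j for j in range(table.n_taxa)
            if Fraction(int(present[j]), table.n_samples) >= frac]
    return AbundanceTable(
        counts=table.counts[:, keep],
        taxonomy=[table.taxonomy[j] for j in keep],
        sample_ids=list(table.sample_ids),
        taxon_ids=[table.taxon_ids[j] for j in keep],
    )


def to_relative_abundance(table: AbundanceTable) -> CompositionTable:
    """Divide each count by its sample total; rows sum to 1."""
    totals = table.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ParameterError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count"
        )
    rel = table.counts / totals[:, None]
    return CompositionTable(
        relabund=rel,
        genus_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
    )


def prepare_microbiome(table: AbundanceTable, min_prevalence=Fraction(3, 10),
                       order: str = "filter-first") -> CompositionTable:
    """Genus aggregation, prevalence filtering and normalization in one call.

    ``order="filter-first"`` (default) filters counts then normalizes, so
    retained genera renormalize to sum 1.  ``order="normalize-first"``
    computes proportions on the full genus table and then drops
    low-prevalence columns without renormalizing.
    """
    genus = aggregate_to_genus(table)
    if order == "filter-first":
        return to_relative_abundance(prevalence_filter(genus, min_prevalence))
    if order == "normalize-first":
        comp = to_relative_abundance(genus)
        kept = set(prevalence_filter(genus, min_prevalence).taxon_ids)
        keep = [j for j, g in enumerate(comp.genus_ids) if g in kept]
        return CompositionTable(
            relabund=comp.relabund[:, keep],
            genus_ids=[comp.genus_ids[j] for j in keep],
            sample_ids=list(comp.sample_ids),
            renormalized=False,
        )
    raise ParameterError(f"unknown order {order!r}")


def write_composition(comp: CompositionTable, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(comp.relabund, index=pd.Index(comp.sample_ids, name="sample_id"),
                      columns=comp.genus_ids)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


def read_composition(path) -> CompositionTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    rel = df.to_numpy(dtype=float)
    renorm = bool(np.allclose(rel.sum(axis=1), 1.0, atol=1e-9))
    return CompositionTable(
        relabund=rel,
        genus_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        renormalized=renorm,
    )
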