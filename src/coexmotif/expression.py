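"""Expression-matrix I/O, validation and subsetting.

The on-disk format is a rectangular TSV: a header row of sample ids, then one
row per gene (gene id first).  Missing entries carry a configurable token
(default ``NA``); in memory they are represented by an explicit boolean
``observed`` mask and the corresponding ``values`` cells are NaN and must
never be read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateInputError, ParseError

DEFAULT_MISSING_TOKEN = "NA"


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with an explicit observed-value mask."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        g, s = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (g, s) or self.observed.shape != (g, s):
            raise ContractError("values/observed shape does not match ids")
        if len(set(self.gene_ids)) != g:
            raise ContractError("duplicate gene ids")
        if len(set(self.sample_ids)) != s:
            raise ContractError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def require_minimum_size(self, min_genes: int = 2, min_samples: int = 4) -> None:
        if self.n_genes < min_genes or self.n_samples < min_samples:
            raise DegenerateInputError(
                f"matrix is {self.n_genes} genes x {self.n_samples} samples; "
                f"need at least {min_genes} x {min_samples}"
            )

    @property
    def fully_observed(self) -> bool:
        return bool(self.observed.all())


@dataclass
class AnnotationSet:
    """Flat gene annotations: GO-like terms and category flags."""

    go_terms: dict[str, set[str]] = field(default_factory=dict)
    categories: dict[str, set[str]] = field(default_factory=dict)

    def genes_in_category(self, category: str) -> set[str]:
        return {g for g, cats in self.categories.items() if category in cats}


VALID_CATEGORIES = {"regulatory", "dna_binding"}


def read_expression(path, missing_token: str = DEFAULT_MISSING_TOKEN) -> ExpressionMatrix:
    """Read a genes-x-samples TSV with a sample-id header row.

    Raises :class:`ParseError` (naming the offending line) on ragged rows,
    duplicated ids or non-numeric, non-missing cells.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:] if header and header[0] == "" else header
    # tolerate an optional corner label in the header
    if len(lines) > 1:
        first_row_cells = lines[1].split("\t")
        if len(first_row_cells) == len(header) and header[0] != "":
            sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}:1: duplicate sample ids in header")
    n_samples = len(sample_ids)

    gene_ids: list[str] = []
    seen: set[str] = set()
    rows: list[np.ndarray] = []
    mask_rows: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_samples + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {n_samples + 1} columns, got {len(cells)}"
            )
        gene = cells[0]
        if gene in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        vals = np.empty(n_samples, dtype=float)
        obs = np.ones(n_samples, dtype=bool)
        for j, cell in enumerate(cells[1:]):
            if cell == missing_token:
                vals[j] = np.nan
                obs[j] = False
            else:
                try:
                    vals[j] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {j + 2}"
                    ) from None
        gene_ids.append(gene)
        rows.append(vals)
        mask_rows.append(obs)
    if not rows:
        raise ParseError(f"{path}: no gene rows")
    m = ExpressionMatrix(gene_ids, list(sample_ids), np.vstack(rows), np.vstack(mask_rows))
    m.require_minimum_size()
    return m


def write_expression(m: ExpressionMatrix, path, missing_token: str = DEFAULT_MISSING_TOKEN) -> None:
    """Write the TSV form; floats use shortest round-trip repr."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(m.sample_ids) + "\n")
        for i, gene in enumerate(m.gene_ids):
            cells = [
                repr(float(m.values[i, j])) if m.observed[i, j] else missing_token
                for j in range(m.n_samples)
            ]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def complete_sample_subset(m: ExpressionMatrix) -> ExpressionMatrix:
    """Retain exactly the samples whose column has no missing entry."""
    keep = m.observed.all(axis=0)
    if not keep.any():
        raise DegenerateInputError("every sample contains at least one missing value")
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        list(m.gene_ids),
        [m.sample_ids[j] for j in idx],
        m.values[:, idx].copy(),
        m.observed[:, idx].copy(),
    )


def filter_min_observations(m: ExpressionMatrix, min_obs: int = 20) -> ExpressionMatrix:
    """Drop genes observed in fewer than ``min_obs`` samples, order preserved."""
    if min_obs < 2:
        raise ContractError("min_obs must be >= 2")
    keep = m.observed.sum(axis=1) >= min_obs
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        [m.gene_ids[i] for i in idx],
        list(m.sample_ids),
        m.values[idx, :].copy(),
        m.observed[idx, :].copy(),
    )


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Read a two-column gene TAB term file into a gene -> term-set map."""
    out: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            out.setdefault(cells[0], set()).add(cells[1])
    return out


def read_annotations(go_path=None, category_path=None) -> AnnotationSet:
    """Assemble an :class:`AnnotationSet` from GO and category TSV files."""
    go = read_annotation_tsv(go_path) if go_path is not None else {}
    cats = read_annotation_tsv(category_path) if category_path is not None else {}
    for gene, cset in cats.items():
        bad = cset - VALID_CATEGORIES
        if bad:
            raise ParseError(f"{category_path}: gene {gene!r} has unknown categories {sorted(bad)}")
    return AnnotationSet(go_terms=go, categories=cats)


def write_annotation_tsv(mapping: dict[str, set[str]], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in sorted(mapping):
            for term in sorted(mapping[gene]):
                fh.write(f"{gene}\t{term}\n")
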