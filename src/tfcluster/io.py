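"""Reading, validation, and deterministic writing of expression data.

An expression matrix is genes x samples, log-scale normalized upstream
(e.g. RMA); the loader only checks structural validity, it never
transforms values. Gene and TF identifiers are opaque, case-sensitive
strings: no normalization is attempted because real inputs mix
identifier schemes (RefSeq, AGI, ...).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TFSet",
    "load_expression",
    "load_tf_list",
    "write_table",
]

#: Tokens treated as missing values in expression files.
MISSING_TOKENS = frozenset({"", "NA", "N/A", "NaN", "nan", "NULL", "null"})


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes x samples matrix.

    Attributes
    ----------
    gene_ids : tuple of str
        Unique row identifiers, order as loaded (length ``q``).
    sample_ids : tuple of str
        Unique column identifiers (length ``m``).
    values : numpy.ndarray
        ``(q, m)`` float array; every entry finite.
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        vals = np.asarray(self.values, dtype=float)
        if len(set(genes)) != len(genes):
            dup = _first_duplicate(genes)
            raise ValueError(f"duplicate gene id {dup!r}")
        if len(set(samples)) != len(samples):
            dup = _first_duplicate(samples)
            raise ValueError(f"duplicate sample id {dup!r}")
        if vals.ndim != 2 or vals.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(samples) < 2:
            raise ValueError("at least 2 samples are required")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {genes[i]!r}, sample {samples[j]!r}"
            )
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.gene_ids)}
            )
            return self._index[gene_id]

    def profile(self, gene_id: str) -> np.ndarray:
        """Expression profile (one value per sample) of ``gene_id``."""
        return self.values[self.index_of(gene_id)]

    def __contains__(self, gene_id: str) -> bool:
        try:
            self.index_of(gene_id)
            return True
        except KeyError:
            return False


@dataclass(frozen=True)
class TFSet:
    """Ordered set of transcription-factor identifiers, all present in the
    companion expression matrix."""

    tf_ids: tuple

    def __post_init__(self):
        ids = tuple(str(t) for t in self.tf_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate TF id {_first_duplicate(ids)!r}")
        if len(ids) < 2:
            raise ValueError("at least 2 TFs are required")
        object.__setattr__(self, "tf_ids", ids)

    def __len__(self) -> int:
        return len(self.tf_ids)

    def __iter__(self):
        return iter(self.tf_ids)

    def __contains__(self, tf_id: str) -> bool:
        return tf_id in set(self.tf_ids)


def _first_duplicate(items: Sequence[str]) -> str:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise ValueError("no duplicate present")


def load_expression(
    path: Union[str, Path],
    dialect: str = "tsv",
    missing: str = "error",
) -> ExpressionMatrix:
    """Load an expression matrix from delimited text.

    The first row is the sample header, the first column holds gene
    identifiers. Row order is preserved.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"tsv", "csv"}
        Field delimiter.
    missing : {"error", "drop-gene"}
        Policy for missing cells (``NA``/empty/...). ``"error"`` aborts;
        ``"drop-gene"`` removes the affected gene rows and warns with a
        count. Association ranks are undefined with holes, so no
        imputation is offered.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    if missing not in ("error", "drop-gene"):
        raise ValueError(f"missing policy must be 'error' or 'drop-gene', got {missing!r}")
    sep = "\t" if dialect == "tsv" else ","
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    gene_ids: list = []
    rows: list = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = [c.strip() for c in header[1:]]
        dropped = 0
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            gid = row[0].strip()
            cells = [c.strip() for c in row[1:]]
            if len(cells) != len(sample_ids):
                raise ValueError(
                    f"{path}:{line_no}: gene {gid!r} has {len(cells)} values, "
                    f"expected {len(sample_ids)}"
                )
            vals = np.empty(len(cells))
            has_missing = False
            for j, cell in enumerate(cells):
                if cell in MISSING_TOKENS:
                    if missing == "error":
                        raise ValueError(
                            f"{path}:{line_no}: missing value for gene {gid!r}, "
                            f"sample {sample_ids[j]!r} (policy=error)"
                        )
                    has_missing = True
                    break
                try:
                    vals[j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{line_no}: non-numeric cell {cell!r} for gene "
                        f"{gid!r}, sample {sample_ids[j]!r}"
                    ) from None
            if has_missing:
                dropped += 1
                continue
            gene_ids.append(gid)
            rows.append(vals)
    if dropped:
        warnings.warn(
            f"dropped {dropped} gene(s) with missing values (policy=drop-gene)",
            UserWarning,
            stacklevel=2,
        )
    if not gene_ids:
        raise ValueError(f"{path}: no usable gene rows")
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), np.vstack(rows))


def load_tf_list(path: Union[str, Path], expr: ExpressionMatrix) -> TFSet:
    """Load TF identifiers (one per line, ``#`` comments ignored), keep those
    present in ``expr`` in file order, and warn about the rest."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    present = set(expr.gene_ids)
    kept: list = []
    seen = set()
    absent: list = []
    for line in path.read_text().splitlines():
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        if tok in seen:
            continue
        seen.add(tok)
        if tok in present:
            kept.append(tok)
        else:
            absent.append(tok)
    if absent:
        warnings.warn(
            f"{len(absent)} TF id(s) absent from the expression matrix were "
            f"dropped: {', '.join(absent[:10])}"
            + ("..." if len(absent) > 10 else ""),
            UserWarning,
            stacklevel=2,
        )
    if not kept:
        raise ValueError(f"{path}: no usable TF identifiers")
    if len(kept) == 1:
        raise ValueError(
            f"{path}: only one usable TF ({kept[0]!r}); at least 2 are required"
        )
    return TFSet(tuple(kept))


def format_float(x: float) -> str:
    """Render a float with 6 significant digits ('.' decimal, no exponent
    surprises for the magnitudes this pipeline emits)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if math.isnan(x):
        return "NA"
    return format(float(x), ".6g")


def write_table(
    records: Union[pd.DataFrame, Iterable[Mapping]],
    path: Union[str, Path],
    columns: Sequence[str] = None,
) -> None:
    """Write tabular records as byte-stable TSV (Unix newlines, fixed float
    formatting). ``records`` may be a DataFrame or an iterable of dicts;
    an empty record set with explicit ``columns`` yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        cols = list(columns) if columns is not None else list(records.columns)
        rows = records.to_dict("records")
    else:
        rows = list(records)
        if columns is not None:
            cols = list(columns)
        elif rows:
            cols = list(rows[0].keys())
        else:
            raise ValueError("empty records require explicit columns")
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in rows:
            cells = []
            for c in cols:
                v = rec[c]
                if isinstance(v, (float, np.floating)):
                    cells.append(format_float(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
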