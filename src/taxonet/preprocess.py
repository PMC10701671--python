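"""Feature-table ingestion and upstream quality control.

In-memory containers are plain pandas objects:

* an **abundance table** is an integer :class:`~pandas.DataFrame` indexed by
  feature id (rows) with one column per sample;
* a **relative abundance table** is its float analogue whose columns each
  sum to one;
* sample **metadata** is a DataFrame indexed by sample id with numeric
  environmental variables and categorical groupings as columns.

The quality-control sequence mirrors common amplicon practice: remove
contaminants flagged by extraction-batch negative controls, drop singleton
features, rarefy to a common depth, then normalise to relative abundance.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TableFormatError",
    "BatchMap",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "read_metadata",
    "read_batch_map",
    "remove_contaminants",
    "remove_singletons",
    "rarefy",
    "to_relative_abundance",
    "scale_metadata",
    "log10_compositions",
]


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


# ---------------------------------------------------------------------------
# batch map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BatchMap:
    """Assignment of samples to DNA-extraction batches.

    Each batch carries a disjoint set of environmental samples and a set of
    negative-control samples; every sample belongs to exactly one batch and
    every batch has at least one environmental sample.
    """

    batch_of: Mapping[str, str]
    environmental: Mapping[str, frozenset]
    controls: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for batch, env in self.environmental.items():
            if not env:
                raise ValueError(f"batch {batch!r} has no environmental samples")
            ctrl = self.controls.get(batch, frozenset())
            if env & ctrl:
                raise ValueError(
                    f"batch {batch!r}: samples {sorted(env & ctrl)} are both "
                    "environmental and control"
                )
        seen: dict[str, str] = {}
        for batch in self.environmental:
            for s in self.environmental[batch] | self.controls.get(batch, frozenset()):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in batches {seen[s]!r} and {batch!r}")
                seen[s] = batch

    @property
    def batch_ids(self) -> list[str]:
        return sorted(self.environmental)

    @property
    def all_controls(self) -> frozenset:
        out: set = set()
        for ctrl in self.controls.values():
            out |= ctrl
        return frozenset(out)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BatchMap":
        """Build from a long table with columns sample-id, batch, role."""
        required = {"sample-id", "batch", "role"}
        if not required.issubset(frame.columns):
            raise TableFormatError(
                f"batch map needs columns {sorted(required)}, got {list(frame.columns)}"
            )
        bad = set(frame["role"]) - {"sample", "control"}
        if bad:
            raise TableFormatError(f"batch map roles must be 'sample' or 'control', got {sorted(bad)}")
        env: dict[str, set] = {}
        ctrl: dict[str, set] = {}
        batch_of: dict[str, str] = {}
        for _, row in frame.iterrows():
            sid, batch, role = str(row["sample-id"]), str(row["batch"]), row["role"]
            batch_of[sid] = batch
            target = env if role == "sample" else ctrl
            target.setdefault(batch, set()).add(sid)
            (ctrl if role == "sample" else env).setdefault(batch, set())
        return cls(
            batch_of=batch_of,
            environmental={b: frozenset(s) for b, s in env.items()},
            controls={b: frozenset(s) for b, s in ctrl.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for batch in self.batch_ids:
            for sid in sorted(self.environmental[batch]):
                rows.append((sid, batch, "sample"))
            for sid in sorted(self.controls.get(batch, frozenset())):
                rows.append((sid, batch, "control"))
        return pd.DataFrame(rows, columns=["sample-id", "batch", "role"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return fh.read().splitlines()


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature × sample count table from TSV.

    The first column holds feature ids and the header row holds sample ids.
    A leading ``# Constructed from biom file`` banner line is tolerated.
    Cells must be non-negative integers.
    """
    lines = [ln for ln in _read_tsv_lines(path) if ln.strip()]
    if lines and lines[0].startswith("#") and "biom" in lines[0].lower():
        lines = lines[1:]
    if not lines:
        raise TableFormatError(f"{path}: empty feature table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise TableFormatError(f"{path}: header has no sample columns")
    sample_ids = header[1:]
    dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dupes:
        raise TableFormatError(f"{path}: duplicate sample ids {sorted(dupes)}")
    feature_ids: list[str] = []
    data: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise TableFormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        fid = cells[0]
        if fid in feature_ids:
            raise TableFormatError(f"{path}:{lineno}: duplicate feature id {fid!r}")
        row: list[int] = []
        for sid, cell in zip(sample_ids, cells[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric count for feature {fid!r}, sample {sid!r}: {cell!r}"
                ) from None
            if np.isnan(value):
                raise TableFormatError(f"{path}: NaN count for feature {fid!r}, sample {sid!r}")
            if value < 0:
                raise TableFormatError(f"{path}: negative count for feature {fid!r}, sample {sid!r}")
            if value != int(value):
                raise TableFormatError(
                    f"{path}: non-integer count for feature {fid!r}, sample {sid!r}: {cell!r}"
                )
            row.append(int(value))
        feature_ids.append(fid)
        data.append(row)
    if not feature_ids:
        raise TableFormatError(f"{path}: feature table has no feature rows")
    return pd.DataFrame(data, index=pd.Index(feature_ids, name="feature-id"), columns=sample_ids)


def write_feature_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "feature-id"
    out.to_csv(path, sep="\t")


_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


def read_taxonomy(path) -> dict[str, tuple[str, ...]]:
    """Read a two-column taxonomy TSV into ``{feature_id: lineage}``.

    Lineages are semicolon-delimited with up to seven ranks; Silva-style
    ``d__``/``p__`` prefixes are stripped.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().replace(" ", ""): c for c in frame.columns}
    fid_col = cols.get("featureid") or cols.get("feature-id") or frame.columns[0]
    tax_col = cols.get("taxon") or frame.columns[1]
    out: dict[str, tuple[str, ...]] = {}
    for _, row in frame.iterrows():
        fid = str(row[fid_col])
        if fid in out:
            raise TableFormatError(f"{path}: duplicate feature id {fid!r} in taxonomy")
        ranks = tuple(
            _RANK_PREFIX.sub("", r.strip()) for r in str(row[tax_col]).split(";") if r.strip()
        )
        if len(ranks) > 7:
            raise TableFormatError(f"{path}: lineage for {fid!r} has {len(ranks)} ranks (max 7)")
        out[fid] = ranks
    return out


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (first column sample-id).

    A secondary ``#q2:types`` header row is tolerated and skipped. Columns
    that parse fully as numbers become numeric; others stay categorical.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame = frame.rename(columns={frame.columns[0]: "sample-id"})
    frame = frame[~frame["sample-id"].astype(str).str.startswith("#")]
    frame = frame.set_index("sample-id")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate sample ids {dupes}")
    out = {}
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        non_missing = frame[col].notna() & (frame[col].astype(str).str.strip() != "")
        if (numeric.notna() | ~non_missing).all():
            out[col] = numeric
        else:
            out[col] = frame[col]
    return pd.DataFrame(out, index=frame.index)


def read_batch_map(path) -> BatchMap:
    return BatchMap.from_frame(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def remove_contaminants(
    table: pd.DataFrame,
    batches: BatchMap,
    fold: float = 10.0,
    control_norm: str = "controls",
    scope: str = "batch",
) -> tuple[pd.DataFrame, list[str]]:
    """Zero out features flagged as contaminants by negative controls.

    Per batch, each feature's abundance is normalised by the number of
    environmental samples in the batch; control abundance is normalised by
    the number of controls (``control_norm='controls'``, default) or by the
    number of environmental samples (``control_norm='env'``). A feature
    detected in a batch's controls is a contaminant in that batch when its
    normalised environmental abundance is less than ``fold`` times its
    normalised control abundance; its counts are then zeroed in every sample
    of that batch (``scope='batch'``) or everywhere (``scope='global'``).

    Control columns are dropped from the result, as are features left with
    all-zero rows. Returns the cleaned table and the sorted list of feature
    ids that were flagged in at least one batch.
    """
    if fold <= 0:
        raise ValueError(f"fold must be positive, got {fold}")
    if control_norm not in {"controls", "env"}:
        raise ValueError(f"control_norm must be 'controls' or 'env', got {control_norm!r}")
    if scope not in {"batch", "global"}:
        raise ValueError(f"scope must be 'batch' or 'global', got {scope!r}")
    out = table.copy()
    removed: set[str] = set()
    for batch in batches.batch_ids:
        env = sorted(s for s in batches.environmental[batch] if s in out.columns)
        ctrl = sorted(batches.controls.get(batch, frozenset()))
        missing = [s for s in ctrl if s not in out.columns]
        if missing:
            raise ValueError(f"batch {batch!r}: control samples {missing} not in table")
        if not env:
            raise ValueError(f"batch {batch!r} has no environmental samples in the table")
        if not ctrl:
            continue
        ctrl_total = out[ctrl].sum(axis=1)
        env_norm = out[env].sum(axis=1) / len(env)
        denom = len(ctrl) if control_norm == "controls" else len(env)
        ctrl_norm = ctrl_total / denom
        flagged = out.index[(ctrl_total > 0) & (env_norm < fold * ctrl_norm)]
        if len(flagged):
            if scope == "batch":
                out.loc[flagged, env] = 0
            else:
                out.loc[flagged, :] = 0
            removed |= set(flagged)
    out = out.drop(columns=[c for c in batches.all_controls if c in out.columns])
    out = out.loc[out.sum(axis=1) > 0]
    return out, sorted(removed)


def remove_singletons(table: pd.DataFrame, mode: str = "total") -> pd.DataFrame:
    """Drop singleton features.

    ``mode='total'`` (default) drops features whose summed count across all
    samples equals one; ``mode='samples'`` drops features detected in
    exactly one sample regardless of count.
    """
    if mode == "total":
        keep = table.sum(axis=1) != 1
    elif mode == "samples":
        keep = (table > 0).sum(axis=1) != 1
    else:
        raise ValueError(f"mode must be 'total' or 'samples', got {mode!r}")
    return table.loc[keep]


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged). The draw is
    multivariate hypergeometric, i.e. an unweighted subsample of the reads
    themselves, and is deterministic for a given seed.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    kept: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sample in table.columns:
        counts = table[sample].to_numpy(dtype=np.int64)
        if counts.sum() < depth:
            dropped.append(sample)
            continue
        kept[sample] = rng.multivariate_hypergeometric(counts, depth)
    if not kept:
        raise ValueError("no samples survive rarefaction")
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    return pd.DataFrame(kept, index=table.index)


def to_relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total so columns sum to one."""
    totals = table.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    return table.astype(float) / totals


def scale_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Rescale each numeric variable to percent of its observed range.

    Each numeric column is mapped to ``100 * (v - min) / (max - min)``;
    missing values stay missing; constant columns are dropped with a
    warning; non-numeric columns are excluded.
    """
    numeric = meta.select_dtypes(include=[np.number])
    out = {}
    for col in numeric.columns:
        values = numeric[col].astype(float)
        finite = values.dropna()
        if not np.isfinite(finite).all():
            raise ValueError(f"metadata variable {col!r} has non-finite values")
        lo, hi = finite.min(), finite.max()
        if len(finite) < 2 or lo == hi:
            warnings.warn(f"dropping constant metadata variable {col!r}", stacklevel=2)
            continue
        out[col] = 100.0 * (values - lo) / (hi - lo)
    return pd.DataFrame(out, index=meta.index)


def log10_compositions(rel: pd.DataFrame, pseudo: float | str = "auto") -> pd.DataFrame:
    """Log10-transform a relative abundance table.

    Zeros are replaced by ``pseudo`` before the transform; ``'auto'`` uses
    half the smallest non-zero proportion in the whole table.
    """
    values = rel.to_numpy(dtype=float)
    if pseudo == "auto":
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError("table has no non-zero proportions")
        pseudo_value = nonzero.min() / 2.0
    else:
        pseudo_value = float(pseudo)
        if pseudo_value <= 0:
            raise ValueError(f"pseudo must be positive, got {pseudo}")
    filled = np.where(values > 0, values, pseudo_value)
    return pd.DataFrame(np.log10(filled), index=rel.index, columns=rel.columns)
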