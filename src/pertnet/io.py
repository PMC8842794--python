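"""Readers, writers and validated domain types for the pipeline's file formats.

All gene identifiers are matched case-sensitively by exact string; no
identifier conversion is performed. Missing expression values are rejected
rather than imputed — the reader fails naming the offending cell.

Formats (all plain text):

* expression matrix — TSV, first column gene/probe id, header row of sample
  ids; a companion two-column TSV maps sample to group label
* gene sets — GMT (name, description, then members, tab-separated)
* interaction network — two-column TSV edge list, collapsed to an
  undirected simple graph
* clinical table — TSV with mandatory columns ``sample``, ``time``, ``event``
* TF targets — TSV with columns ``regulator``, ``class``, ``target``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

INTENSITY = "intensity"
COUNTS = "counts"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A gene×sample expression matrix with per-sample group labels.

    ``values`` is a pandas DataFrame (rows = genes or probes, columns =
    samples). ``flavor`` declares the value scale: ``"intensity"`` for log2
    intensities or ``"counts"`` for raw non-negative integer counts.
    ``probe_to_gene`` optionally maps row ids (probes) to gene symbols for
    the probe-collapse step.
    """

    values: pd.DataFrame
    group_of: dict[str, str]
    flavor: str = INTENSITY
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.flavor not in (INTENSITY, COUNTS):
            raise FormatError(f"unknown expression flavor {self.flavor!r}")
        cols = list(self.values.columns)
        dupes = _duplicates(cols)
        if dupes:
            raise FormatError(f"duplicate sample ids: {sorted(dupes)}")
        gdupes = _duplicates(list(self.values.index))
        if gdupes:
            raise FormatError(f"duplicate gene/probe ids: {sorted(gdupes)[:10]}")
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise FormatError(f"samples missing from group file: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if self.flavor == COUNTS:
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise FormatError("counts flavor requires non-negative integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == label]


@dataclass
class GeneSetCollection:
    """Named gene sets; member order is preserved for deterministic output."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            d = _duplicates(members)
            if d:
                # dedup silently is the reader's job; constructor keeps strict
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])


@dataclass
class SurvivalCohort:
    """Per-sample survival time/event joined to an expression matrix.

    ``time`` and ``event`` are pandas Series indexed by sample id; the
    expression frame carries one column per sample of the cohort.
    """

    time: pd.Series
    event: pd.Series
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.time.index.equals(self.event.index):
            raise FormatError("time and event must share a sample index")
        if (self.time <= 0).any():
            bad = self.time.index[self.time <= 0][0]
            raise FormatError(f"non-positive survival time for sample {bad!r}")
        if not set(np.unique(self.event)).issubset({0, 1}):
            raise FormatError("event indicator must be 0 (censored) or 1 (death)")
        missing = [s for s in self.time.index if s not in self.expression.columns]
        if missing:
            raise FormatError(f"samples missing expression: {missing[:10]}")

    @property
    def samples(self) -> list[str]:
        return list(self.time.index)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def covariate(self, gene: str) -> np.ndarray:
        if gene not in self.expression.index:
            raise DataError(f"gene {gene!r} not in cohort expression")
        return self.expression.loc[gene, self.samples].to_numpy(dtype=float)


@dataclass
class TFTargetMap:
    """Regulator → target-set annotation with a TF / cofactor class tag."""

    targets: dict[str, set[str]]
    class_of: dict[str, str]

    def __post_init__(self) -> None:
        for reg, tset in self.targets.items():
            if not tset:
                raise FormatError(f"regulator {reg!r} has an empty target set")
            if reg not in self.class_of:
                raise FormatError(f"regulator {reg!r} has no class tag")
        bad = {c for c in self.class_of.values() if c not in ("TF", "cofactor")}
        if bad:
            raise FormatError(f"unknown regulator classes: {sorted(bad)}")

    @property
    def regulators(self) -> list[str]:
        return list(self.targets)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _read_lines(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return fh.read().splitlines()


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_group_file(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→group TSV (header ``sample<TAB>group``)."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty group file")
    out: dict[str, str] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{i}: expected 'sample<TAB>group'")
        if parts[0] in out:
            raise FormatError(f"{path}:{i}: duplicate sample {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


def read_expression_matrix(
    path: str | Path,
    group_file: str | Path,
    flavor: str = INTENSITY,
    probe_map: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix plus its sample→group file.

    The first column holds gene/probe ids; the header row holds sample ids.
    Row order is preserved. Duplicate sample ids, samples missing from the
    group file and non-numeric cells are format errors.
    """
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    samples = header[1:]
    dupes = _duplicates(samples)
    if dupes:
        raise FormatError(f"{path}: duplicate sample ids in header: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        num = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        ) from None
    groups = read_group_file(group_file)
    missing = [s for s in samples if s not in groups]
    if missing:
        raise FormatError(f"{path}: samples missing from group file: {missing}")
    p2g = dict(read_tsv_map(probe_map)) if probe_map else None
    return ExpressionMatrix(
        values=num,
        group_of={s: groups[s] for s in samples},
        flavor=flavor,
        probe_to_gene=p2g,
    )


def read_tsv_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (with header) read into an ordered mapping."""
    out: dict[str, str] = {}
    for i, line in enumerate(_read_lines(path)[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected two tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def write_expression_matrix(
    em: ExpressionMatrix, path: str | Path, group_path: str | Path
) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
    with open(group_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s in em.sample_ids:
            fh.write(f"{s}\t{em.group_of[s]}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB members...``."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for i, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs >=3 fields")
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}:{i}: duplicate gene set name {name!r}")
        members = list(dict.fromkeys(m for m in parts[2:] if m))
        if not members:
            raise FormatError(f"{path}:{i}: gene set {name!r} has no members")
        sets[name] = members
        desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll.sets.items():
            d = coll.descriptions.get(name, "")
            fh.write("\t".join([name, d, *members]) + "\n")


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, directed_input: bool = True) -> nx.Graph:
    """Read a two-column TSV edge list into an undirected simple graph.

    A directed input is collapsed to undirected; self-loops are dropped and
    parallel/reciprocal edges merged, with dropped counts logged. Collapsing
    therefore never increases the edge count.
    """
    g = nx.Graph()
    loops = 0
    dups = 0
    for i, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{i}: expected two non-blank endpoints")
        u, v = parts[0], parts[1]
        if u == v:
            loops += 1
            continue
        if g.has_edge(u, v):
            dups += 1
            continue
        g.add_edge(u, v)
    if loops or dups:
        logger.info(
            "read_edge_list(%s): dropped %d self-loops, merged %d duplicate/"
            "reciprocal edges (directed_input=%s)", path, loops, dups, directed_input
        )
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# clinical table / survival cohort
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with mandatory columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    dupes = _duplicates(list(df["sample"].astype(str)))
    if dupes:
        raise FormatError(f"{path}: duplicate samples: {sorted(dupes)}")
    return df


def build_cohort(clinical: pd.DataFrame, expr: ExpressionMatrix) -> SurvivalCohort:
    """Join a clinical table to an expression matrix on sample id.

    Clinical samples without expression are dropped with a logged count.
    """
    clin = clinical.set_index(clinical["sample"].astype(str))
    have = [s for s in clin.index if s in expr.values.columns]
    dropped = len(clin) - len(have)
    if dropped:
        logger.info("build_cohort: dropped %d clinical samples without expression", dropped)
    clin = clin.loc[have]
    return SurvivalCohort(
        time=clin["time"].astype(float),
        event=clin["event"].astype(int),
        expression=expr.values[have],
    )


def write_clinical(cohort: SurvivalCohort, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample": cohort.samples,
         "time": cohort.time.to_numpy(),
         "event": cohort.event.to_numpy()}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# TF target table
# ---------------------------------------------------------------------------

def read_tf_targets(path: str | Path) -> TFTargetMap:
    """Read a TSV with columns regulator, class, target (one pair per row)."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty TF target file")
    targets: dict[str, set[str]] = {}
    class_of: dict[str, str] = {}
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: expected regulator, class, target")
        reg, cls, tgt = parts[0], parts[1], parts[2]
        if reg in class_of and class_of[reg] != cls:
            raise FormatError(f"{path}:{i}: regulator {reg!r} has conflicting classes")
        class_of[reg] = cls
        targets.setdefault(reg, set()).add(tgt)
    return TFTargetMap(targets=targets, class_of=class_of)


def write_tf_targets(tfmap: TFTargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\tclass\ttarget\n")
        for reg in sorted(tfmap.targets):
            for tgt in sorted(tfmap.targets[reg]):
                fh.write(f"{reg}\t{tfmap.class_of[reg]}\t{tgt}\n")
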