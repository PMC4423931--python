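"""Readers and writers for the tab-delimited interchange formats.

Dialects
--------
CNV tables carry genomic positions either 1-based inclusive (the convention
of hg19 coordinates printed in the literature, and the default here) or
0-based half-open. BED files are always 0-based half-open per the BED
standard. Whatever the input dialect, intervals are normalised to 0-based
half-open in memory, and writing in the same dialect round-trips the file
coordinates exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import (
    AUTOSOMES,
    STATE_ALIASES,
    OTHER,
    CnvCall,
    FormatError,
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    RecordError,
    Region,
    RegionSet,
    SampleRecord,
    GeneSet,
    normalize_chrom,
)

log = logging.getLogger(__name__)

ONE_BASED = "1-based"
ZERO_BASED = "0-based"

CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "probes", "state"]

#: column mapping for PLINK ``.cnv`` files
PLINK_CNV_COLUMN_MAP = {
    "IID": "sample_id", "CHR": "chrom", "BP1": "start", "BP2": "end",
    "SITES": "probes", "TYPE": "state",
}


def _normalise_start(start: int, dialect: str) -> int:
    if dialect == ONE_BASED:
        return start - 1
    if dialect == ZERO_BASED:
        return start
    raise ValueError(f"unknown dialect {dialect!r}")


def read_cnv_table(
    path,
    dialect: str = ONE_BASED,
    column_map: Optional[dict] = None,
) -> list[CnvCall]:
    """Read a tab-delimited CNV call table into :class:`CnvCall` records.

    Parameters
    ----------
    path : path-like
        File with header ``sample_id  chrom  start  end  probes  state``.
    dialect : str
        Coordinate convention of the *input* (``"1-based"`` inclusive, the
        default, or ``"0-based"`` half-open).
    column_map : dict, optional
        Mapping from the file's column names to the canonical names, e.g.
        :data:`PLINK_CNV_COLUMN_MAP` for PLINK ``.cnv`` files.

    Non-autosomal records (X/Y/MT) are excluded by design with a logged
    count; malformed rows raise :class:`RecordError` with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    for col in CNV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"CNV table {path}: missing required column {col!r}")
    calls: list[CnvCall] = []
    n_nonautosomal = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        chrom = normalize_chrom(getattr(row, "chrom"))
        if chrom not in AUTOSOMES:
            n_nonautosomal += 1
            continue
        try:
            start = _normalise_start(int(getattr(row, "start")), dialect)
            end = int(getattr(row, "end"))
            probes = int(getattr(row, "probes"))
        except (TypeError, ValueError) as exc:
            raise RecordError(f"non-numeric field: {exc}", line=line) from exc
        if start < 0:
            raise RecordError(f"negative start {start}", line=line)
        if start >= end:
            raise RecordError(
                f"start >= end after normalisation ({start} >= {end})", line=line
            )
        state = STATE_ALIASES.get(str(getattr(row, "state")).strip().lower(), OTHER)
        calls.append(
            CnvCall(
                sample_id=str(getattr(row, "sample_id")),
                interval=GenomicInterval(chrom, start, end),
                probe_count=probes,
                state=state,
            )
        )
    if n_nonautosomal:
        log.warning(
            "%s: excluded %d non-autosomal record(s) (X/Y out of scope)",
            path, n_nonautosomal,
        )
    return calls


def write_cnv_table(calls: Sequence[CnvCall], path, dialect: str = ONE_BASED) -> None:
    offset = 1 if dialect == ONE_BASED else 0
    state_out = {"deletion": "del", "duplication": "dup", "other": "other"}
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.interval.chrom,
            "start": c.interval.start + offset,
            "end": c.interval.end,
            "probes": c.probe_count,
            "state": state_out[c.state],
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> list[SampleRecord]:
    """Read ``sample_id  cohort  [sex]  [syndrome]`` (tab-delimited)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "cohort"):
        if col not in df.columns:
            raise FormatError(f"sample table {path}: missing column {col!r}")
    samples = []
    for row in df.itertuples(index=False):
        sex = getattr(row, "sex", None)
        syndrome = getattr(row, "syndrome", None)
        samples.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                cohort=str(row.cohort),
                sex=None if pd.isna(sex) else sex,
                syndrome=None if pd.isna(syndrome) else syndrome,
            )
        )
    return samples


def write_sample_table(samples: Sequence[SampleRecord], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "cohort": s.cohort,
             "sex": s.sex or "", "syndrome": s.syndrome or ""}
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_region_bed(path, name: str) -> RegionSet:
    """Read a BED3/BED4(+gene) file into a :class:`RegionSet`.

    Coordinates are 0-based half-open per the BED standard. The optional
    4th column becomes the region label (default ``<name>_<i>``); an
    optional 5th column is kept as a candidate-gene tag.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: expected >= 3 BED columns")
            chrom = normalize_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: non-integer position") from exc
            if start < 0:
                raise FormatError(f"{path} line {lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path} line {lineno}: start >= end")
            label = fields[3] if len(fields) >= 4 and fields[3] else f"{name}_{lineno}"
            gene = fields[4] if len(fields) >= 5 and fields[4] else None
            regions.append(Region(label, GenomicInterval(chrom, start, end), gene))
    if not regions:
        log.warning("%s: empty region file for %r", path, name)
    return RegionSet(name, regions)


def write_region_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.interval.chrom, str(r.interval.start), str(r.interval.end), r.label]
            if r.gene:
                cols.append(r.gene)
            fh.write("\t".join(cols) + "\n")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read ``symbol  chrom  start  end  brain_expressed{0,1}`` (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("symbol", "chrom", "start", "end", "brain_expressed"):
        if col not in df.columns:
            raise FormatError(f"gene annotation {path}: missing column {col!r}")
    genes = [
        GeneModel(
            symbol=str(row.symbol),
            span=GenomicInterval(
                normalize_chrom(row.chrom), int(row.start), int(row.end)
            ),
            brain_expressed=str(row.brain_expressed).strip() in ("1", "True", "true"),
        )
        for row in df.itertuples(index=False)
    ]
    return GeneAnnotation(genes)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    pd.DataFrame(
        [
            {
                "symbol": g.symbol, "chrom": g.span.chrom,
                "start": g.span.start, "end": g.span.end,
                "brain_expressed": int(g.brain_expressed),
            }
            for g in annotation
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; ``#`` comments allowed."""
    symbols = set()
    with open(path) as fh:
        for raw in fh:
            s = raw.split("#", 1)[0].strip()
            if s:
                symbols.add(s)
    return GeneSet(name or Path(path).stem, frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for s in sorted(gene_set.symbols):
            fh.write(s + "\n")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT term library: ``term <tab> description <tab> gene...``."""
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.rstrip("\n")
            if not s.strip():
                continue
            fields = s.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: expected >= 3 GMT columns")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_ppi_edges(edges: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
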