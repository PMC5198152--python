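"""CSV/FASTA round-tripping for the pipeline's tabular interfaces.

Formats:
  peak tables    CSV with header sample_id,replicate,enzyme,size_bp,area
  T-RF matrix    CSV, samples as rows (index column sample_id), integer bins
  reference db   CSV with taxon_label,sequence_id,enzyme,trf_bp
  process table  CSV, samples as rows, one column per parameter; blank = missing
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .insilico import ReferenceTaxon, refdb_from_frame, refdb_to_frame
from .profiles import Peak, PeakTable, TRFMatrix

PEAK_COLUMNS = ["sample_id", "replicate", "enzyme", "size_bp", "area"]


def read_peak_tables(path) -> list[PeakTable]:
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak-table CSV missing columns: {sorted(missing)}")
    tables = []
    for (sid, rep, enz), grp in df.groupby(["sample_id", "replicate", "enzyme"],
                                           sort=False):
        peaks = [Peak(size_bp=float(r.size_bp), area=float(r.area))
                 for r in grp.itertuples()]
        tables.append(PeakTable(sample_id=str(sid), replicate=int(rep),
                                enzyme_name=str(enz), peaks=peaks))
    return tables


def write_peak_tables(tables: list[PeakTable], path) -> None:
    rows = [(t.sample_id, t.replicate, t.enzyme_name, p.size_bp, p.area)
            for t in tables for p in t.peaks]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


def read_trf_matrix(path, enzyme_name: str) -> TRFMatrix:
    df = pd.read_csv(path, index_col=0)
    df.columns = [int(c) for c in df.columns]
    return TRFMatrix.from_frame(df, enzyme_name)


def write_trf_matrix(matrix: TRFMatrix, path) -> None:
    matrix.to_frame().to_csv(path, float_format="%.10g")


def read_refdb(path) -> list[ReferenceTaxon]:
    return refdb_from_frame(pd.read_csv(path))


def write_refdb(taxa: list[ReferenceTaxon], path) -> None:
    refdb_to_frame(taxa).to_csv(path, index=False)


def read_process_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_process_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, float_format="%.10g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
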