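"""Readers/writers for the plain-text table formats.

Communities and references are CSV/TSV; score tables are CSV plus a JSON
metadata sidecar (see :class:`biomon.biotic.ScoreTable`); trait tables are
CSV plus a JSON block definition.  Aggregated communities serialize to a
single JSON document so CLI steps can be chained.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biotic import ScoreTable
from .ranks import RANKS, REF_COLUMNS
from .taxonomy import (
    AggregatedCommunity,
    CommunityMatrix,
    MatchReport,
    ReferenceDataset,
    ValidationError,
)
from .traits import TraitDataset


def _read_table(path: str | Path, delimiter: str | None, decimal: str) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=delimiter, decimal=decimal, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"cannot read {path}: {exc}") from exc


def read_community(
    path: str | Path,
    delimiter: str | None = None,
    decimal: str = ".",
    occurrence: bool = False,
) -> CommunityMatrix:
    """First column: taxon names; remaining columns: numeric samples."""
    raw = _read_table(path, delimiter, decimal)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: community needs a taxon column plus samples")
    taxa = raw.iloc[:, 0].astype(str)
    data = {}
    for col in raw.columns[1:]:
        vals = []
        for i, cell in enumerate(raw[col]):
            text = str(cell).strip()
            if decimal != ".":
                text = text.replace(decimal, ".")
            try:
                vals.append(float(text))
            except ValueError:
                raise ValidationError(
                    f"{path}: malformed numeric cell at row {i + 2}, "
                    f"column {col!r}: {cell!r}"
                ) from None
        data[col] = vals
    df = pd.DataFrame(data, index=list(taxa))
    return CommunityMatrix(df, occurrence)


def write_community(cm: CommunityMatrix, path: str | Path, delimiter: str = ",") -> None:
    out = cm.df.copy()
    out.insert(0, "Taxon", out.index)
    out.to_csv(path, sep=delimiter, index=False)


def read_reference(
    path: str | Path, delimiter: str | None = None
) -> ReferenceDataset:
    """Header row names ranks exactly; empty string = missing rank."""
    raw = _read_table(path, delimiter, ".")
    missing = [c for c in REF_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: reference missing columns {missing}")
    return ReferenceDataset(raw.fillna(""))


def write_reference(ref: ReferenceDataset, path: str | Path, delimiter: str = ",") -> None:
    ref.df.to_csv(path, sep=delimiter, index=False)


def read_scores(path: str | Path) -> ScoreTable:
    table = ScoreTable.from_csv(path)
    problems = table.validate()
    if problems:
        raise ValidationError(f"{path}: {'; '.join(problems)}")
    return table


def write_scores(table: ScoreTable, path: str | Path) -> None:
    table.to_csv(path)


def read_traits(
    csv_path: str | Path, blocks_path: str | Path | None = None
) -> TraitDataset:
    """Trait CSV: taxon, rank, then modality columns; block definition JSON
    maps trait -> list of modality columns (defaults to one block per
    column prefix before the final underscore)."""
    raw = _read_table(csv_path, None, ".")
    if "taxon" not in raw.columns or "rank" not in raw.columns:
        raise ValidationError(f"{csv_path}: traits need 'taxon' and 'rank' columns")
    mods = [c for c in raw.columns if c not in {"taxon", "rank"}]
    if blocks_path is not None:
        blocks = {
            k: list(v) for k, v in json.loads(Path(blocks_path).read_text()).items()
        }
    else:
        blocks = {}
        for c in mods:
            trait = c.rsplit("_", 1)[0]
            blocks.setdefault(trait, []).append(c)
    data = raw.set_index("taxon")[mods].astype(float)
    data.index.name = None
    ranks = raw.set_index("taxon")["rank"]
    ranks.index.name = None
    ranks.name = None
    return TraitDataset(data, ranks, blocks)


def write_traits(
    traits: TraitDataset, csv_path: str | Path, blocks_path: str | Path | None = None
) -> None:
    out = traits.data.copy()
    out.insert(0, "rank", traits.ranks)
    out.insert(0, "taxon", out.index)
    out.to_csv(csv_path, index=False)
    if blocks_path is not None:
        Path(blocks_path).write_text(json.dumps(traits.blocks, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# AggregatedCommunity JSON
# ---------------------------------------------------------------------------


def _frame_to_obj(df: pd.DataFrame) -> dict:
    return {
        "index": list(df.index),
        "columns": list(df.columns),
        "values": df.to_numpy(dtype=float).tolist(),
    }


def _frame_from_obj(obj: dict) -> pd.DataFrame:
    return pd.DataFrame(
        np.asarray(obj["values"], dtype=float).reshape(
            len(obj["index"]), len(obj["columns"])
        ),
        index=obj["index"],
        columns=obj["columns"],
    )


def agg_to_json(agg: AggregatedCommunity) -> str:
    return json.dumps(
        {
            "samples": agg.samples,
            "occurrence": agg.occurrence,
            "per_rank": {r: _frame_to_obj(cm.df) for r, cm in agg.per_rank.items()},
            "taxa_table": _frame_to_obj(agg.taxa_table.df),
            "reference": agg.reference.df.to_dict(orient="list"),
            "match_report": json.loads(agg.match_report.to_json()),
        },
        indent=2,
        sort_keys=True,
    )


def agg_from_json(text: str) -> AggregatedCommunity:
    obj = json.loads(text)
    ref = ReferenceDataset(pd.DataFrame(obj["reference"]))
    report = MatchReport.from_json(json.dumps(obj["match_report"]))
    occurrence = obj["occurrence"]
    per_rank = {
        r: CommunityMatrix(_frame_from_obj(o), occurrence)
        for r, o in obj["per_rank"].items()
    }
    # preserve canonical rank order
    per_rank = {r: per_rank[r] for r in RANKS if r in per_rank} | {
        r: cm for r, cm in per_rank.items() if r not in RANKS
    }
    return AggregatedCommunity(
        per_rank,
        CommunityMatrix(_frame_from_obj(obj["taxa_table"]), occurrence),
        ref,
        report,
        obj["samples"],
        occurrence,
    )


def save_agg(agg: AggregatedCommunity, path: str | Path) -> None:
    Path(path).write_text(agg_to_json(agg))


def load_agg(path: str | Path) -> AggregatedCommunity:
    return agg_from_json(Path(path).read_text())
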