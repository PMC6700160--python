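"""Plain-text readers/writers: matrix TSV, design TSV, BED-like annotation,
GMT gene sets, result tables.

Matrices are features x samples with the feature id in the first column.
Annotation files are written 1-based inclusive (noted in a header comment);
in-memory coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import FeatureAnnotation, OmicsDataset, StudyDesign
from .enrichment import GeneSetCollection


def write_matrix(data: OmicsDataset, path: str | Path) -> None:
    data.values.rename_axis("feature_id").to_csv(path, sep="\t")


def read_matrix(path: str | Path, dataset_id: str, modality: str) -> OmicsDataset:
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values.index = values.index.astype(str)
    return OmicsDataset(dataset_id=dataset_id, modality=modality, values=values)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> StudyDesign:
    t = pd.read_csv(path, sep="\t", comment="#",
                    dtype={"sample_id": str, "individual_id": str,
                           "dataset_id": str, "group": str, "sex": str})
    return StudyDesign(t)


ANNOTATION_HEADER = "# coordinates: 1-based, inclusive\n"
_ANN_COLS = ["chrom", "start", "end", "feature_id", "feature_type", "strand"]


def write_annotations(ann: FeatureAnnotation, path: str | Path) -> None:
    """BED-like 6-column TSV, converted to 1-based inclusive coordinates."""
    t = ann.table.copy()
    is_probe = t["feature_type"] == "probe"
    t["start"] = t["start"] + 1                      # 0-based -> 1-based
    t.loc[is_probe, "end"] = t.loc[is_probe, "end"] + 1
    with open(path, "w") as fh:
        fh.write(ANNOTATION_HEADER)
        t[_ANN_COLS].to_csv(fh, sep="\t", index=False)


def read_annotations(path: str | Path) -> FeatureAnnotation:
    t = pd.read_csv(path, sep="\t", comment="#",
                    dtype={"chrom": str, "feature_id": str,
                           "feature_type": str, "strand": str})
    is_probe = t["feature_type"] == "probe"
    t["start"] = t["start"] - 1                      # 1-based -> 0-based
    t.loc[is_probe, "end"] = t.loc[is_probe, "end"] - 1
    cols = ["feature_id", "feature_type", "chrom", "start", "end", "strand"]
    return FeatureAnnotation(t[cols])


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = set(parts[2:])
    return GeneSetCollection(sets=sets, universe=set(universe or ()))


def write_table(table: pd.DataFrame, path: str | Path, header_comment: str | None = None,
                index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=index)
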