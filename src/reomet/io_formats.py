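"""Readers and writers for the tabular formats the pipeline consumes.

Expression matrices are TSV with genes as rows and a header of sample ids;
mutations arrive as MAF-style tables; copy-number calls as GISTIC-style
gene/region x sample tables (continuous or already thresholded); regulatory
edges as two-column TSV or SIF; gene sets as GMT.  All loaders enforce the
type invariants (unique ids, finite values, legal categories) up front so
downstream stages can assume clean inputs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reo_classifier import GenePairSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "MutationMatrix",
    "CNAMatrix",
    "CNACallConfig",
    "RegionGeneMap",
    "GeneSetCollection",
    "DEFAULT_NONSYN_CLASSES",
    "read_expression",
    "write_expression",
    "collapse_probes",
    "read_maf",
    "read_gistic",
    "read_clinical",
    "write_clinical",
    "read_signature",
    "write_signature",
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_region_map",
    "write_region_map",
]

DAYS_PER_MONTH = 30.44

#: MAF Variant_Classification values counted as protein-altering by default.
DEFAULT_NONSYN_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

_STAGE_MAJOR = {"IA": "IA", "IB": "IB", "II": "II", "III": "III", "IV": "IV"}


def _check_unique(ids: Sequence, what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValueError(f"duplicate {what} identifiers: {sorted(map(str, dupes.index))}")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples."""

    values_frame: pd.DataFrame

    def __post_init__(self) -> None:
        vf = self.values_frame
        _check_unique(list(vf.index), "gene")
        _check_unique(list(vf.columns), "sample")
        if vf.shape[0] < 1 or vf.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=1 gene and >=2 samples, got {vf.shape}"
            )
        if not np.isfinite(vf.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values_frame.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values_frame.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values_frame.shape


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations indexed by sample_id."""

    frame: pd.DataFrame

    REQUIRED = ("stage", "metastasis_clinical")
    OPTIONAL = (
        "age",
        "gender",
        "os_time",
        "os_event",
        "rfs_time",
        "rfs_event",
        "adjuvant",
        "subtype",
        "smoking",
    )

    def __post_init__(self) -> None:
        f = self.frame
        _check_unique(list(f.index), "sample")
        for col in ("os_time", "rfs_time"):
            if col in f.columns:
                vals = f[col].dropna()
                if (vals < 0).any():
                    raise ValueError(f"{col} contains negative times")
        for col in ("os_event", "rfs_event"):
            if col in f.columns:
                vals = f[col].dropna()
                if not vals.isin([0, 1]).all():
                    raise ValueError(f"{col} must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]


@dataclass
class MutationMatrix:
    """Binary gene x sample matrix; 1 = at least one qualifying mutation."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.calls.index), "gene")
        _check_unique(list(self.calls.columns), "sample")
        if not self.calls.isin([0, 1]).all().all():
            raise ValueError("mutation calls must be binary")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.calls.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.calls.columns]


@dataclass(frozen=True)
class CNACallConfig:
    amp_threshold: float = 0.3
    del_threshold: float = -0.3

    def __post_init__(self) -> None:
        if not self.del_threshold < 0 < self.amp_threshold:
            raise ValueError("thresholds must satisfy del < 0 < amp")


@dataclass
class CNAMatrix:
    """{-1, 0, +1} copy-number calls, lesion (gene or region) x sample."""

    calls: pd.DataFrame
    call_config: CNACallConfig = field(default_factory=CNACallConfig)

    def __post_init__(self) -> None:
        _check_unique(list(self.calls.index), "lesion")
        _check_unique(list(self.calls.columns), "sample")
        if not self.calls.isin([-1, 0, 1]).all().all():
            raise ValueError("CNA calls must be in {-1, 0, +1}")

    @property
    def lesion_ids(self) -> list[str]:
        return [str(g) for g in self.calls.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.calls.columns]


@dataclass
class RegionGeneMap:
    """Region id -> member gene ids (many-to-many)."""

    members: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for region, genes in self.members.items():
            if len(genes) < 1:
                raise ValueError(f"region {region!r} has no member genes")

    def genes_for(self, region: str) -> tuple[str, ...]:
        # gene-level lesions pass through as their own single-member region
        return self.members.get(region, (region,))


@dataclass
class GeneSetCollection:
    """set_id -> (description, gene tuple); genes deduplicated per set."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for sid, (_, genes) in self.sets.items():
            if len(genes) < 1:
                raise ValueError(f"gene set {sid!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {sid!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, missing_policy: str = "error") -> ExpressionMatrix:
    """Read a genes-x-samples TSV.

    missing_policy='error' raises on any missing/non-numeric cell with its
    coordinates; 'drop_gene' drops the offending rows with a logged warning.
    """
    if missing_policy not in ("error", "drop_gene"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(list(raw.index), "gene")
    _check_unique(list(raw.columns), "sample")
    frame = raw.apply(pd.to_numeric, errors="coerce")
    bad = frame.isna() | ~np.isfinite(frame.fillna(0.0))
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        coords = [(str(frame.index[r]), str(frame.columns[c])) for r, c in zip(rows, cols)]
        if missing_policy == "error":
            raise ValueError(f"non-numeric or missing cells at {coords[:10]}")
        bad_genes = sorted({g for g, _ in coords})
        logger.warning("dropping %d gene(s) with missing values: %s", len(bad_genes), bad_genes[:10])
        frame = frame.drop(index=bad_genes)
    return ExpressionMatrix(frame.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values_frame.to_csv(path, sep="\t", index_label="gene_id")


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str | Sequence[str]],
) -> ExpressionMatrix:
    """Average probe rows mapping to the same gene; drop probes mapping to
    zero or more than one gene."""
    frame = probe_matrix.values_frame
    gene_of: dict[str, str] = {}
    for probe, genes in probe_to_gene.items():
        targets = [genes] if isinstance(genes, str) else list(genes)
        if len(targets) == 1:
            gene_of[probe] = targets[0]
    kept = [p for p in frame.index if p in gene_of]
    if not kept:
        raise ValueError("no probe maps uniquely to a gene")
    sub = frame.loc[kept]
    collapsed = sub.groupby([gene_of[p] for p in kept], sort=False).mean()
    collapsed.index.name = frame.index.name
    return ExpressionMatrix(collapsed)


# ---------------------------------------------------------------------------
# mutations


def read_maf(
    path: str | Path,
    nonsyn_classes: Iterable[str] = DEFAULT_NONSYN_CLASSES,
    allow_empty: bool = False,
) -> MutationMatrix:
    """Build a binary mutation matrix from a MAF-style TSV.

    A (gene, sample) entry is 1 iff at least one row of that pair carries a
    Variant_Classification in ``nonsyn_classes``.  Samples present in the
    file but with no qualifying rows appear as all-zero columns.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"):
        if col not in table.columns:
            raise ValueError(f"MAF is missing required column {col!r}")
    if table.empty:
        if allow_empty:
            return MutationMatrix(pd.DataFrame(dtype=int))
        raise ValueError("MAF body is empty")
    classes = set(nonsyn_classes)
    keep = table[table["Variant_Classification"].isin(classes)]
    samples = sorted(table["Tumor_Sample_Barcode"].unique())
    genes = sorted(keep["Hugo_Symbol"].unique())
    calls = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for gene, sample in zip(keep["Hugo_Symbol"], keep["Tumor_Sample_Barcode"]):
        calls.loc[gene, sample] = 1
    calls.index.name = "gene_id"
    return MutationMatrix(calls)


def write_mutation_matrix(muts: MutationMatrix, path: str | Path) -> None:
    muts.calls.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# copy number


def read_gistic(
    path: str | Path,
    call_config: CNACallConfig | None = None,
    dialect: str = "auto",
) -> CNAMatrix:
    """Read a lesion x sample copy-number table and threshold to calls.

    Continuous values map to +1 above ``amp_threshold`` (strict), -1 below
    ``del_threshold`` (strict), else 0.  Already-discrete tables (all values
    in {-2,-1,0,1,2}) are collapsed to sign.  The function is idempotent on
    its own output.
    """
    cfg = call_config or CNACallConfig()
    if dialect not in ("auto", "continuous", "discrete"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    values = frame.to_numpy()
    discrete_like = np.isin(values, [-2.0, -1.0, 0.0, 1.0, 2.0]).all()
    if dialect == "discrete" and not discrete_like:
        off = values[~np.isin(values, [-2.0, -1.0, 0.0, 1.0, 2.0])]
        raise ValueError(f"discrete dialect but found values like {off.flat[0]!r}")
    if discrete_like and dialect != "continuous":
        calls = np.sign(values).astype(int)
    else:
        calls = np.zeros_like(values, dtype=int)
        calls[values > cfg.amp_threshold] = 1
        calls[values < cfg.del_threshold] = -1
    out = pd.DataFrame(calls, index=frame.index.astype(str), columns=frame.columns.astype(str))
    out.index.name = "lesion_id"
    return CNAMatrix(out, cfg)


def write_cna_matrix(cna: CNAMatrix, path: str | Path) -> None:
    cna.calls.to_csv(path, sep="\t", index_label="lesion_id")


# ---------------------------------------------------------------------------
# clinical


def _normalize_stage(label: str) -> str:
    s = str(label).strip().upper()
    for major in ("IV", "III", "II", "IB", "IA"):
        if s == major or (s.startswith(major) and major in ("IV", "III", "II")):
            return _STAGE_MAJOR[major]
    # sub-stages of IA/IB such as IA1
    m = re.fullmatch(r"(I[AB])\d*", s)
    if m:
        return _STAGE_MAJOR[m.group(1)]
    raise ValueError(f"unknown stage label {label!r}")


def read_clinical(path: str | Path, time_unit: str = "months") -> ClinicalTable:
    """Read a clinical TSV keyed by sample_id.

    ``time_unit='days'`` converts survival times to months (/30.44).
    """
    if time_unit not in ("months", "days"):
        raise ValueError(f"unknown time_unit {time_unit!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in frame.columns:
        raise ValueError("clinical table must have a sample_id column")
    frame = frame.set_index("sample_id")
    if "stage" in frame.columns:
        frame["stage"] = [_normalize_stage(s) if pd.notna(s) else s for s in frame["stage"]]
    for col in ("age", "os_time", "os_event", "rfs_time", "rfs_event"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    if time_unit == "days":
        for col in ("os_time", "rfs_time"):
            if col in frame.columns:
                frame[col] = frame[col] / DAYS_PER_MONTH
    for col in ("metastasis_clinical",):
        if col in frame.columns:
            vals = frame[col].dropna()
            bad = set(vals.unique()) - {"yes", "no"}
            if bad:
                raise ValueError(f"metastasis_clinical must be yes/no, got {sorted(bad)}")
    return ClinicalTable(frame)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# signature / network / gene sets / region map


def read_signature(path: str | Path) -> GenePairSignature:
    """TSV with columns gene_high (vote-high gene) and gene_low."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_high", "gene_low"):
        if col not in frame.columns:
            raise ValueError(f"signature file missing column {col!r}")
    pairs = tuple((str(a), str(b)) for a, b in zip(frame["gene_high"], frame["gene_low"]))
    return GenePairSignature(pairs)


def write_signature(sig: GenePairSignature, path: str | Path) -> None:
    pd.DataFrame(sig.pairs, columns=["gene_high", "gene_low"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path: str | Path) -> list[tuple[str, str]]:
    """Directed regulator->target edges from 2-column TSV or 3-column SIF."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("regulator", "source"):  # header
                continue
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                # SIF: source relation target [target ...]
                edges.extend((parts[0], t) for t in parts[2:])
            else:
                raise ValueError(f"malformed edge at line {lineno}: {line!r}")
    return edges


def write_network(edges: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need id, desc, >=1 gene")
            sid, desc, genes = parts[0], parts[1], parts[2:]
            deduped = tuple(dict.fromkeys(g for g in genes if g))
            sets[sid] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, genes) in collection.items():
            fh.write("\t".join([sid, desc, *genes]) + "\n")


def read_region_map(path: str | Path) -> RegionGeneMap:
    """Two-column TSV: region_id, gene_id (one row per membership)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"region_id", "gene_id"}.issubset(frame.columns):
        raise ValueError("region map needs region_id and gene_id columns")
    members: dict[str, tuple[str, ...]] = {}
    for region, group in frame.groupby("region_id", sort=False):
        members[str(region)] = tuple(dict.fromkeys(group["gene_id"]))
    return RegionGeneMap(members)


def write_region_map(region_map: RegionGeneMap, path: str | Path) -> None:
    rows = [
        {"region_id": region, "gene_id": gene}
        for region, genes in region_map.members.items()
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["region_id", "gene_id"]).to_csv(path, sep="\t", index=False)
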