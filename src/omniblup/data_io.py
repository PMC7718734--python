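"""Readers, writers and line-identifier alignment for every format the pipeline touches.

Conventions: TSV is tab-separated with '.' decimals and "NA" as the missing
token; variant positions and gene spans are 1-based (VCF / GFF3 convention,
spans inclusive). Inbred-panel VCF genotypes are collapsed to line dosages
(hom-ref -> 0, hom-alt -> 2); residual heterozygous calls are treated as
no-calls by default because the panels modelled here are fully inbred.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GO_ID_RE = re.compile(r"^GO:\d{7}$")
NA_TOKEN = "NA"


class DataFormatError(ValueError):
    """A file violated its declared dialect; the message names the record."""


def _check_unique(line_ids: Sequence[str], what: str) -> None:
    seen = pd.Index(line_ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise DataFormatError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Lines x variants allele-dosage table for an inbred panel.

    ``dosages`` is float with NaN for missing calls; non-missing values come
    from the declared coding (``{0, max_dosage}`` for homozygous panels,
    optionally intermediate heterozygote dosage).
    """

    line_ids: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    max_dosage: float = 2.0

    def __post_init__(self) -> None:
        _check_unique(self.line_ids, "line")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.variants)):
            raise ValueError("dosage shape does not match line/variant counts")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["id"])

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, computed on non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing column
            p = np.nanmean(self.dosages, axis=0) / self.max_dosage
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            dosages=self.dosages[:, keep],
            variants=self.variants.iloc[keep].reset_index(drop=True),
            max_dosage=self.max_dosage,
        )

    def subset_lines(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in idx],
            dosages=self.dosages[idx],
            variants=self.variants,
            max_dosage=self.max_dosage,
        )


@dataclass
class ExpressionMatrix:
    """Lines x genes abundance table on the log2FPKM scale."""

    line_ids: list[str]
    abundances: np.ndarray
    genes: pd.DataFrame  # columns: id (plus optional chrom/start/end)

    def __post_init__(self) -> None:
        _check_unique(self.line_ids, "line")
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.line_ids), len(self.genes)):
            raise ValueError("abundance shape does not match line/gene counts")
        if not np.all(np.isfinite(self.abundances)):
            i, j = np.argwhere(~np.isfinite(self.abundances))[0]
            raise DataFormatError(
                f"non-finite expression value at line {self.line_ids[i]!r}, "
                f"gene {self.genes['id'].iloc[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["id"])

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            line_ids=list(self.line_ids),
            abundances=self.abundances[:, keep],
            genes=self.genes.iloc[keep].reset_index(drop=True),
        )

    def subset_lines(self, idx: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            line_ids=[self.line_ids[i] for i in idx],
            abundances=self.abundances[idx],
            genes=self.genes,
        )


@dataclass
class PhenotypeTable:
    """Line-mean phenotypes (NaN where a line lacks a trait) plus covariates."""

    line_ids: list[str]
    traits: pd.DataFrame
    covariates: pd.DataFrame | None = None
    dropped_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.line_ids, "line")
        if len(self.traits) != len(self.line_ids):
            raise ValueError("trait table length does not match line count")

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def trait_values(self, trait: str) -> np.ndarray:
        return self.traits[trait].to_numpy(dtype=float)

    def missing_mask(self, trait: str) -> np.ndarray:
        return self.traits[trait].isna().to_numpy()

    def subset_lines(self, idx: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(
            line_ids=[self.line_ids[i] for i in idx],
            traits=self.traits.iloc[idx].reset_index(drop=True),
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[idx].reset_index(drop=True),
            dropped_lines=list(self.dropped_lines),
        )


@dataclass
class AnnotationMap:
    """Gene -> GO terms, gene spans, and (filled by preprocess) variant -> genes."""

    gene_to_terms: dict[str, set[str]]
    gene_spans: dict[str, tuple[str, int, int]]
    variant_to_gene: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                if not GO_ID_RE.match(t):
                    raise DataFormatError(f"malformed GO id {t!r} for gene {g!r}")
        for g, (chrom, start, end) in self.gene_spans.items():
            if start > end:
                raise DataFormatError(f"gene {g!r}: span start {start} > end {end}")

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out

    def term_to_genes(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                inv.setdefault(t, set()).add(g)
        return inv


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    het_policy: str = "missing",
    on_multiallelic: str = "error",
    variants_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read line genotypes from a VCF or a dosage TSV.

    ``het_policy``: 'missing' treats residual heterozygous calls in an inbred
    panel as no-calls; 'half' codes them as dosage 1. ``on_multiallelic``:
    'error' rejects the file naming the record, 'drop' silently skips such
    sites.
    """
    if format == "vcf":
        return _read_vcf(Path(path), het_policy, on_multiallelic)
    if format == "dosage_tsv":
        return _read_dosage_tsv(Path(path), variants_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, het_policy: str, on_multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    het_dosage = np.nan if het_policy == "missing" else 1.0
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    lut = np.array([0.0, het_dosage, np.nan, 2.0])

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    _check_unique(samples, "sample")
    rows = []
    recs = []
    for v in vcf:
        if len(v.ALT) != 1:
            if on_multiallelic == "drop":
                continue
            raise DataFormatError(
                f"multiallelic record at {v.CHROM}:{v.POS} and decomposition disabled"
            )
        rows.append(lut[np.asarray(v.gt_types)])
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        recs.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
    vcf.close()
    variants = pd.DataFrame(recs, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(line_ids=samples, dosages=dosages, variants=variants)


_VARIANT_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[^:]+):(?P<alt>[^:]+)$")


def _read_dosage_tsv(path: Path, variants_path: str | Path | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False,
                     float_precision="round_trip")
    try:
        dosages = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataFormatError(f"non-numeric dosage cell in {path}: {exc}") from exc
    ids = [str(c) for c in df.columns]
    if variants_path is not None:
        variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        missing_cols = {"id", "chrom", "pos", "ref", "alt"} - set(variants.columns)
        if missing_cols:
            raise DataFormatError(f"variant metadata missing columns {sorted(missing_cols)}")
        variants = variants.set_index("id").loc[ids].reset_index()
    else:
        recs = []
        for i, vid in enumerate(ids):
            m = _VARIANT_ID_RE.match(vid)
            if m:
                recs.append((vid, m["chrom"], int(m["pos"]), m["ref"], m["alt"]))
            else:
                recs.append((vid, "un", i + 1, "N", "N"))
        variants = pd.DataFrame(recs, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(line_ids=[str(i) for i in df.index], dosages=dosages, variants=variants)


def read_matrix_table(path: str | Path, kind: str) -> ExpressionMatrix | PhenotypeTable | pd.DataFrame:
    """Read a lines-in-rows TSV as an expression, phenotype, or covariate table."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False,
                     float_precision="round_trip")
    line_ids = [str(i) for i in df.index]
    if kind == "expression":
        arr = df.to_numpy()
        if arr.dtype == object:
            for j, col in enumerate(df.columns):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    i = int(np.flatnonzero(bad.to_numpy())[0])
                    raise DataFormatError(
                        f"non-numeric expression cell at line {line_ids[i]!r}, "
                        f"gene {col!r}: {df[col].iloc[i]!r}"
                    )
            arr = df.apply(pd.to_numeric).to_numpy()
        if np.isnan(arr.astype(float)).any():
            i, j = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise DataFormatError(
                f"missing expression value at line {line_ids[i]!r}, gene {df.columns[j]!r}"
            )
        genes = pd.DataFrame({"id": [str(c) for c in df.columns]})
        return ExpressionMatrix(line_ids=line_ids, abundances=arr.astype(float), genes=genes)
    if kind == "phenotype":
        traits = df.apply(pd.to_numeric).reset_index(drop=True)
        return PhenotypeTable(line_ids=line_ids, traits=traits)
    if kind == "covariates":
        return df
    raise ValueError(f"unknown table kind {kind!r}")


def read_annotation(
    gene2go_path: str | Path, gene_span_path: str | Path
) -> AnnotationMap:
    """Read a gene->GO two-column TSV and gene spans (GFF3 or 4-column TSV)."""
    gene_to_terms: dict[str, set[str]] = {}
    with open(gene2go_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataFormatError(f"{gene2go_path}:{ln}: expected 2 columns")
            gene, term = parts[0], parts[1]
            if ln == 1 and gene.lower() in ("gene", "gene_id") and not GO_ID_RE.match(term):
                continue  # header
            if not GO_ID_RE.match(term):
                raise DataFormatError(f"{gene2go_path}:{ln}: malformed GO id {term!r}")
            gene_to_terms.setdefault(gene, set()).add(term)

    span_path = Path(gene_span_path)
    if span_path.suffix.lower() in (".gff", ".gff3"):
        gene_spans = _read_gff3_gene_spans(span_path)
    else:
        gene_spans = _read_span_tsv(span_path)
    # genes present in spans but absent from gene2go keep an empty term set
    for g in gene_spans:
        gene_to_terms.setdefault(g, set())
    return AnnotationMap(gene_to_terms=gene_to_terms, gene_spans=gene_spans)


def _read_gff3_gene_spans(path: Path) -> dict[str, tuple[str, int, int]]:
    from gffutils.iterators import DataIterator

    spans: dict[str, tuple[str, int, int]] = {}
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gid = (feat.attributes.get("ID") or feat.attributes.get("gene_id") or [feat.id])[0]
        if feat.start > feat.end:
            raise DataFormatError(f"{path}: gene {gid!r} has start {feat.start} > end {feat.end}")
        spans[gid] = (feat.seqid, int(feat.start), int(feat.end))
    return spans


def _read_span_tsv(path: Path) -> dict[str, tuple[str, int, int]]:
    spans: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataFormatError(f"{path}:{ln}: expected 4 columns")
            gene, chrom, start_s, end_s = parts[:4]
            if ln == 1 and not (start_s.isdigit() and end_s.isdigit()):
                continue  # header
            start, end = int(start_s), int(end_s)
            if start > end:
                raise DataFormatError(f"{path}:{ln}: gene {gene!r} span start > end")
            spans[gene] = (chrom, start, end)
    return spans


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_results(results, path: str | Path, format: str = "tsv") -> Path:
    """Serialize pipeline outputs; numeric round trips are exact (repr floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df = _as_frame(results)
        # %.17g round-trips doubles exactly
        df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.17g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_as_jsonable(results), fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown output format {format!r}")
    return path


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if hasattr(results, "folds"):  # CVMetrics
        return results.folds
    if isinstance(results, (list, tuple)) and results and dataclasses.is_dataclass(results[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in results])
    if isinstance(results, Mapping):
        return pd.DataFrame([results])
    raise TypeError(f"cannot serialize {type(results).__name__} to TSV")


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _as_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        items = list(obj)
        if isinstance(obj, set):
            items = sorted(items)
        return [_as_jsonable(v) for v in items]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


# ---------------------------------------------------------------------------
# layer alignment
# ---------------------------------------------------------------------------

@dataclass
class Panel:
    """Aligned multi-layer dataset: all layers share ``line_ids`` in order."""

    line_ids: list[str]
    genotypes: GenotypeMatrix | None = None
    expression: ExpressionMatrix | None = None
    phenotypes: PhenotypeTable | None = None
    annotation: AnnotationMap | None = None
    dropped_ids: dict[str, list[str]] = field(default_factory=dict)


def align_layers(
    genotypes: GenotypeMatrix | None = None,
    expression: ExpressionMatrix | None = None,
    phenotypes: PhenotypeTable | None = None,
    annotation: AnnotationMap | None = None,
) -> Panel:
    """Join layers on the sorted intersection of line ids, recording drops."""
    layers = {
        "genotypes": genotypes,
        "expression": expression,
        "phenotypes": phenotypes,
    }
    present = {k: v for k, v in layers.items() if v is not None}
    if not present:
        raise ValueError("at least one layer required")
    common: set[str] | None = None
    for obj in present.values():
        ids = set(obj.line_ids)
        common = ids if common is None else common & ids
    if not common:
        raise ValueError("line-id intersection across layers is empty")
    keep = sorted(common)
    dropped = {k: sorted(set(v.line_ids) - common) for k, v in present.items()}
    out: dict[str, object] = {}
    for name, obj in present.items():
        pos = {lid: i for i, lid in enumerate(obj.line_ids)}
        idx = np.array([pos[lid] for lid in keep])
        out[name] = obj.subset_lines(idx)
    return Panel(
        line_ids=keep,
        genotypes=out.get("genotypes"),
        expression=out.get("expression"),
        phenotypes=out.get("phenotypes"),
        annotation=annotation,
        dropped_ids=dropped,
    )
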