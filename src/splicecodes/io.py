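"""Readers and writers for the formats the toolkit touches.

Truth datasets, assay read-outs, comparator variants and reports travel
as headered TSV; transcripts come from GTF/GFF3 (via gffutils) or a
simple exon table; variants and their SpliceAI annotations come from VCF
(via pysam, raw or masked annotation dialect) or a TSV fallback.  All
readers fail fast on schema violations with line numbers; skipped records
are always logged, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .calibration import TruthRecord
from .codes import (Classification, Code, CodeSet, CodeStrength,
                    ComparatorVariant, SpliceAIScores)
from .pvs1 import (AssayReadout, AssaySource, AssayTranscript, CriticalDomain,
                   EventType, Frame, GeneContext, RescueTranscript,
                   SpliceEventPrediction)
from .simulate import representative_region
from .transcript import RegionCategory, RegionClass, Side, TranscriptModel, VariantAllele

log = logging.getLogger("splicecodes")

__all__ = [
    "read_truth", "write_truth", "read_transcripts", "read_variants",
    "read_assay", "read_comparators", "read_gene_context",
    "write_report", "read_report", "SchemaError",
]


class SchemaError(ValueError):
    """A required column is missing or a field fails validation."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------- truth data

def read_truth(path: str) -> List[TruthRecord]:
    """Read a calibration truth dataset from headered TSV.

    Required columns: variant_key, score, spliceogenic (0/1).  Optional:
    gene, region (category name), source.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["variant_key", "score", "spliceogenic"], path)
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header + 1-based
        try:
            if "region" in df.columns and pd.notna(row["region"]):
                region = representative_region(RegionCategory(str(row["region"])))
            else:
                region = representative_region(RegionCategory.OUTSIDE)
            records.append(TruthRecord(
                variant_key=str(row["variant_key"]),
                score=float(row["score"]),
                spliceogenic=bool(int(row["spliceogenic"])),
                region=region,
                gene=str(row["gene"]) if "gene" in df.columns and pd.notna(row.get("gene")) else None,
                source=str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else None))
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path}:{line}: {exc}") from exc
    return records


def write_truth(records: Sequence[TruthRecord], path: str) -> None:
    pd.DataFrame([{
        "variant_key": r.variant_key,
        "gene": r.gene or "",
        "score": r.score,
        "spliceogenic": int(r.spliceogenic),
        "region": r.region.category.value,
        "source": r.source or "",
    } for r in records]).to_csv(path, sep="\t", index=False, float_format="%.17g")


# --------------------------------------------------------------- transcripts

def _transcripts_from_gtf(path: str) -> Dict[str, TranscriptModel]:
    import gffutils
    db = gffutils.create_db(path, dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_transcripts=True,
                            disable_infer_genes=True)
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not tids:
            log.warning("%s: %s feature without transcript_id skipped", path,
                        feat.featuretype)
            continue
        for tid in tids:
            meta.setdefault(tid, (feat.seqid, feat.strand))
            target = exons if feat.featuretype == "exon" else cds
            target.setdefault(tid, []).append((feat.start, feat.end))
    out = {}
    for tid, ex in exons.items():
        chrom, strand = meta[tid]
        cds_iv = cds.get(tid)
        kw = {}
        if cds_iv:
            kw["cds_start"] = min(s for s, _ in cds_iv)
            kw["cds_end"] = max(e for _, e in cds_iv)
        out[tid] = TranscriptModel.from_genomic_exons(tid, chrom, strand, ex, **kw)
    return out


def _transcripts_from_tsv(path: str) -> Dict[str, TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["transcript_id", "chrom", "strand", "exon_start", "exon_end"], path)
    out = {}
    for tid, group in df.groupby("transcript_id", sort=False):
        chrom = str(group["chrom"].iloc[0])
        strand = str(group["strand"].iloc[0])
        ex = list(zip(group["exon_start"].astype(int), group["exon_end"].astype(int)))
        out[str(tid)] = TranscriptModel.from_genomic_exons(str(tid), chrom, strand, ex)
    return out


def read_transcripts(path: str) -> Dict[str, TranscriptModel]:
    """Read transcript models from GTF/GFF3 or a headered exon-table TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return _transcripts_from_gtf(path)
    return _transcripts_from_tsv(path)


# ------------------------------------------------------------------ variants

_SPLICEAI_FIELDS = ("allele", "symbol", "ds_ag", "ds_al", "ds_dg", "ds_dl",
                    "dp_ag", "dp_al", "dp_dg", "dp_dl")


def _parse_spliceai_entry(entry: str, alt: str) -> Optional[SpliceAIScores]:
    parts = entry.split("|")
    if len(parts) != len(_SPLICEAI_FIELDS):
        raise ValueError(f"malformed SpliceAI entry with {len(parts)} fields")
    if parts[0] != alt:
        return None
    def f(x: str) -> float:
        return float(x) if x not in ("", ".") else 0.0
    def i(x: str) -> Optional[int]:
        return int(x) if x not in ("", ".") else None
    return SpliceAIScores(ds_ag=f(parts[2]), ds_al=f(parts[3]),
                          ds_dg=f(parts[4]), ds_dl=f(parts[5]),
                          dp_ag=i(parts[6]), dp_al=i(parts[7]),
                          dp_dg=i(parts[8]), dp_dl=i(parts[9]))


def _variants_from_vcf(path: str) -> List[Tuple[VariantAllele, Optional[SpliceAIScores]]]:
    import pysam
    out: List[Tuple[VariantAllele, Optional[SpliceAIScores]]] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            raw = rec.info.get("SpliceAI") if "SpliceAI" in rec.info else None
            entries: List[str] = []
            if raw is not None:
                entries = list(raw) if isinstance(raw, tuple) else [str(raw)]
            for alt in rec.alts or ():
                variant = VariantAllele(str(rec.chrom), int(rec.pos), rec.ref, alt)
                scores = None
                for entry in entries:
                    try:
                        parsed = _parse_spliceai_entry(entry, alt)
                    except ValueError as exc:
                        log.warning("%s: %s at %s:%s; scores ignored",
                                    path, exc, rec.chrom, rec.pos)
                        continue
                    if parsed is not None:
                        scores = parsed
                        break
                if scores is None and entries:
                    log.warning("%s: no SpliceAI entry matches alt %s at %s:%s",
                                path, alt, rec.chrom, rec.pos)
                if not entries:
                    log.warning("%s: missing SpliceAI annotation at %s:%s",
                                path, rec.chrom, rec.pos)
                out.append((variant, scores))
    return out


def _variants_from_tsv(path: str) -> List[Tuple[VariantAllele, Optional[SpliceAIScores]]]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "pos", "ref", "alt",
                          "ds_ag", "ds_al", "ds_dg", "ds_dl"], path)
    out = []
    for idx, row in df.iterrows():
        variant = VariantAllele(str(row["chrom"]), int(row["pos"]),
                                str(row["ref"]), str(row["alt"]))
        if any(pd.isna(row[c]) for c in ("ds_ag", "ds_al", "ds_dg", "ds_dl")):
            log.warning("%s:%d: missing delta scores", path, idx + 2)
            out.append((variant, None))
            continue
        def opt(col: str) -> Optional[int]:
            return int(row[col]) if col in df.columns and pd.notna(row.get(col)) else None
        out.append((variant, SpliceAIScores(
            ds_ag=float(row["ds_ag"]), ds_al=float(row["ds_al"]),
            ds_dg=float(row["ds_dg"]), ds_dl=float(row["ds_dl"]),
            dp_ag=opt("dp_ag"), dp_al=opt("dp_al"),
            dp_dg=opt("dp_dg"), dp_dl=opt("dp_dl"))))
    return out


def read_variants(path: str) -> List[Tuple[VariantAllele, Optional[SpliceAIScores]]]:
    """Read variant alleles with SpliceAI annotations from VCF or TSV.

    Multiallelic VCF records are split into one record per alt allele; an
    annotation entry is only used when its allele field matches the alt.
    """
    if Path(path).suffix.lower() == ".vcf" or path.endswith(".vcf.gz"):
        return _variants_from_vcf(path)
    return _variants_from_tsv(path)


# --------------------------------------------------------------------- assay

_EVENT_ALIASES = {e.value: e for e in EventType}


def read_assay(path: str) -> Optional[AssayReadout]:
    """Read an RNA assay read-out table.

    Required columns: event_type, aberrant_fraction, allele_specific,
    source.  Optional: frame, affected_exons (comma-separated),
    nmd_predicted, fraction_protein_removed, controls_matched_tissue.
    Returns None for an empty table (no RNA evidence).
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return None
    _require_columns(df, ["event_type", "aberrant_fraction", "allele_specific",
                          "source"], path)
    transcripts = []
    sources = set()
    matched = True
    for idx, row in df.iterrows():
        line = idx + 2
        ev = str(row["event_type"]).strip().lower()
        if ev not in _EVENT_ALIASES:
            raise SchemaError(f"{path}:{line}: unknown event_type {ev!r}")
        frame = Frame(str(row["frame"]).strip().lower()) if "frame" in df.columns \
            and pd.notna(row.get("frame")) else Frame.IN_FRAME
        exons: Tuple[int, ...] = ()
        if "affected_exons" in df.columns and pd.notna(row.get("affected_exons")):
            exons = tuple(int(x) for x in str(row["affected_exons"]).split(",") if x != "")
        try:
            pred = SpliceEventPrediction(
                event_type=_EVENT_ALIASES[ev], affected_exons=exons, frame=frame,
                nmd_predicted=bool(int(row["nmd_predicted"]))
                if "nmd_predicted" in df.columns and pd.notna(row.get("nmd_predicted")) else False,
                fraction_protein_removed=float(row["fraction_protein_removed"])
                if "fraction_protein_removed" in df.columns
                and pd.notna(row.get("fraction_protein_removed")) else 0.0)
            transcripts.append(AssayTranscript(
                prediction=pred,
                aberrant_fraction=float(row["aberrant_fraction"]),
                allele_specific=bool(int(row["allele_specific"]))))
        except ValueError as exc:
            raise SchemaError(f"{path}:{line}: {exc}") from exc
        sources.add(str(row["source"]).strip().lower())
        if "controls_matched_tissue" in df.columns and pd.notna(row.get("controls_matched_tissue")):
            matched = matched and bool(int(row["controls_matched_tissue"]))
    if len(sources) > 1:
        raise SchemaError(f"{path}: a read-out must come from a single source, got {sources}")
    try:
        source = AssaySource(sources.pop())
    except ValueError as exc:
        raise SchemaError(f"{path}: unknown assay source: {exc}") from exc
    return AssayReadout(transcripts=tuple(transcripts), source=source,
                        controls_matched_tissue=matched)


# --------------------------------------------------------------- comparators

def read_comparators(path: str) -> List[ComparatorVariant]:
    """Read classified comparator variants for PS1 from TSV.

    Required: variant_key, classification, region, side, offset,
    event_type, prediction_strength.  Optional: exonic, affected_exons,
    cryptic_pos, same_nucleotide, same_motif, clinical_support.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["variant_key", "classification", "region", "side",
                          "offset", "event_type", "prediction_strength"], path)
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        cls_raw = str(row["classification"]).strip().lower()
        try:
            cls = Classification(cls_raw)
        except ValueError:
            raise SchemaError(f"{path}:{line}: unknown classification {cls_raw!r}")
        ev = str(row["event_type"]).strip().lower()
        if ev not in _EVENT_ALIASES:
            raise SchemaError(f"{path}:{line}: unknown event_type {ev!r}")
        try:
            region = RegionClass(
                category=RegionCategory(str(row["region"]).strip().lower()),
                side=Side(str(row["side"]).strip().lower()),
                offset=int(row["offset"]),
                exonic=bool(int(row["exonic"])) if "exonic" in df.columns
                and pd.notna(row.get("exonic")) else False)
            exons: Tuple[int, ...] = ()
            if "affected_exons" in df.columns and pd.notna(row.get("affected_exons")):
                exons = tuple(int(x) for x in str(row["affected_exons"]).split(",") if x != "")
            pred = SpliceEventPrediction(
                event_type=_EVENT_ALIASES[ev], affected_exons=exons,
                position_of_cryptic_site=int(row["cryptic_pos"])
                if "cryptic_pos" in df.columns and pd.notna(row.get("cryptic_pos")) else None)
            out.append(ComparatorVariant(
                variant_key=str(row["variant_key"]), classification=cls,
                region=region, predicted_event=pred,
                prediction_strength=float(row["prediction_strength"]),
                same_nucleotide_as_vua=bool(int(row["same_nucleotide"]))
                if "same_nucleotide" in df.columns and pd.notna(row.get("same_nucleotide")) else False,
                same_motif_as_vua=bool(int(row["same_motif"]))
                if "same_motif" in df.columns and pd.notna(row.get("same_motif")) else False,
                clinical_support_flag=bool(int(row["clinical_support"]))
                if "clinical_support" in df.columns and pd.notna(row.get("clinical_support")) else False))
        except (ValueError, KeyError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{path}:{line}: {exc}") from exc
    return out


# -------------------------------------------------------------- gene context

def read_gene_context(path: str, gene: Optional[str] = None) -> GeneContext:
    """Read a per-gene context configuration from YAML.

    The file maps gene symbols to context blocks; with a single block the
    ``gene`` argument may be omitted.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if gene is None:
        if len(data) != 1:
            raise SchemaError(f"{path}: specify a gene; file has {len(data)} entries")
        gene = next(iter(data))
    if gene not in data:
        raise SchemaError(f"{path}: no configuration for gene {gene!r}")
    blk = data[gene] or {}
    try:
        return GeneContext(
            gene=gene,
            lof_mechanism_established=bool(blk.get("lof_mechanism_established", True)),
            critical_domains=tuple(
                CriticalDomain(start=int(d["start"]), end=int(d["end"]),
                               evidence_tier=str(d.get("evidence_tier", "functional")),
                               pathogenic_missense=bool(d.get("pathogenic_missense", False)))
                for d in blk.get("critical_domains", [])),
            rescue_transcripts=tuple(
                RescueTranscript(transcript_id=str(r["transcript_id"]),
                                 skips_exons=tuple(int(e) for e in r.get("skips_exons", [])),
                                 expression_fraction=float(r["expression_fraction"]),
                                 encodes_functional_protein=bool(
                                     r.get("encodes_functional_protein", True)))
                for r in blk.get("rescue_transcripts", [])),
            protein_size_threshold=float(blk.get("protein_size_threshold", 0.10)),
            rescue_expression_threshold=float(blk.get("rescue_expression_threshold", 0.10)),
            start_loss_upweight=bool(blk.get("start_loss_upweight", False)),
            utr_critical_element=bool(blk.get("utr_critical_element", False)),
            complementary_site_pathogenic=frozenset(
                int(e) for e in blk.get("complementary_site_pathogenic", [])))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid gene context for {gene!r}: {exc}") from exc


# ------------------------------------------------------------------- reports

_REPORT_COLUMNS = ["variant", "transcript", "region", "side", "offset", "exonic",
                   "assigned", "suppressed", "record_only"]


def write_report(rows: Sequence[Tuple[str, str, RegionClass, CodeSet]],
                 path: str) -> None:
    """Write a code-assignment report (one row per variant/transcript)."""
    data = []
    for variant, transcript, region, codes in rows:
        for code, reason in codes.suppressed:
            log.info("%s/%s: %s suppressed: %s", variant, transcript, code, reason)
        data.append({
            "variant": variant,
            "transcript": transcript,
            "region": region.category.value,
            "side": region.side.value,
            "offset": region.offset,
            "exonic": int(region.exonic),
            "assigned": json.dumps([
                {"name": c.name, "strength": c.strength.value, "rna": c.rna,
                 "rationale": c.rationale} for c in codes.assigned]),
            "suppressed": json.dumps(list(codes.suppressed)),
            "record_only": json.dumps(list(codes.record_only)),
        })
    pd.DataFrame(data, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_report(path: str) -> List[Tuple[str, str, RegionClass, CodeSet]]:
    """Parse a report back into CodeSet content (round-trip of write_report)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _REPORT_COLUMNS, path)
    out = []
    for _, row in df.iterrows():
        codes = CodeSet(
            assigned=[Code(name=d["name"], strength=CodeStrength(d["strength"]),
                           rna=bool(d["rna"]), rationale=d["rationale"])
                      for d in json.loads(row["assigned"])],
            suppressed=[tuple(x) for x in json.loads(row["suppressed"])],
            record_only=list(json.loads(row["record_only"])))
        region = RegionClass(RegionCategory(row["region"]), Side(row["side"]),
                             int(row["offset"]), exonic=bool(int(row["exonic"])))
        out.append((str(row["variant"]), str(row["transcript"]), region, codes))
    return out
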