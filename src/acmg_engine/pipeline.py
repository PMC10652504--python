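"""Readers, writers, configuration and the per-variant pipeline driver.

Evidence arrives pre-annotated (JSON, TSV or a minimal annotated VCF);
gene context and threshold overrides come from configuration tables.  The
driver runs, per record: gene gate -> all criterion modules -> conflict
resolution -> rule-based classification + Bayesian posterior, and writes
a JSON audit report plus a TSV summary.  The classification path contains
no randomness; identical inputs produce byte-identical reports.

TSV dialect: tab-separated, UTF-8, header row, ``.`` for missing values.
List-valued evidence uses compact encodings shared with the VCF INFO
mapping (``|`` separates fields within an item, ``,`` separates items in
TSV, ``&`` in VCF INFO):

* frequencies: ``POP|AC|AN|FOUNDER``  e.g. ``NFE|3|100000|0``
* prior_variants: ``CODON|ALT_AA|EQUIV|CLASS|REPORTS`` e.g. ``120|W|1|pathogenic|2``
* recessive_obs: tokens ``in_trans``, ``phase_unknown``, ``hom``, ``hom_consang``
* denovo_obs: ``confirmed|<phenotype>`` or ``assumed|<phenotype>``
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Union

import pandas as pd
import yaml

from . import case_level, insilico, molecular, population
from .classifier import (
    Classification,
    DEFAULT_BA1_POINTS,
    DEFAULT_BOUNDARIES,
    DEFAULT_PRIOR,
    PosteriorBoundaries,
    RecordStatus,
    classify_calls,
)
from .model import (
    ALL_CRITERIA,
    CaseControlStudy,
    CaseLevelData,
    ConfigurationError,
    Criterion,
    CriterionCall,
    DeNovoObservation,
    EvidenceRecord,
    FrequencyRecord,
    FrequencyThresholds,
    GateOutcome,
    GeneContext,
    InsilicoThresholds,
    PhenotypeMatch,
    PriorClassification,
    PriorClassifiedVariant,
    RecessiveObservation,
    RecessivePhase,
    gate_gene,
    unapplied_call,
)
from .molecular import Pvs1Table

logger = logging.getLogger("acmg_engine")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Engine-level settings for a classification run."""

    prior: float = DEFAULT_PRIOR
    caution_cap: int = 2
    ba1_points: int = DEFAULT_BA1_POINTS
    boundaries: PosteriorBoundaries = field(default_factory=PosteriorBoundaries)
    pvs1_table: Optional[Pvs1Table] = None
    genes: dict[str, GeneContext] = field(default_factory=dict)
    output_format: str = "json"
    log_level: str = "INFO"


def load_gene_config(path: Union[str, Path]) -> dict[str, GeneContext]:
    """Load the per-gene context table (YAML or JSON, keyed by symbol)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError("gene config must be a mapping of symbol -> fields")
    genes = {}
    for symbol, fields in raw.items():
        data = dict(fields or {})
        data.setdefault("symbol", symbol)
        genes[symbol] = GeneContext.model_validate(data)
    return genes


def load_threshold_config(
    path: Union[str, Path], genes: dict[str, GeneContext]
) -> dict[str, GeneContext]:
    """Apply a threshold-override config onto a gene table.

    Schema: ``frequency: {SYMBOL: {ba1, bs1_s, pm2_p, pm2_m}}`` and
    ``insilico: {SYMBOL: {revel_pathogenic, ...}}``.  Overrides for genes
    absent from the gene table are a configuration error.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = dict(genes)
    for symbol, fields in (raw.get("frequency") or {}).items():
        if symbol not in out:
            raise ConfigurationError(f"frequency override for unknown gene {symbol}")
        out[symbol] = out[symbol].model_copy(
            update={"frequency_overrides": FrequencyThresholds.model_validate(fields)}
        )
    for symbol, fields in (raw.get("insilico") or {}).items():
        if symbol not in out:
            raise ConfigurationError(f"insilico override for unknown gene {symbol}")
        out[symbol] = out[symbol].model_copy(
            update={"insilico_overrides": InsilicoThresholds.model_validate(fields)}
        )
    return out


def demo_gene_table() -> dict[str, GeneContext]:
    """The small gene-context table bundled with the package."""
    from importlib import resources

    text = resources.files("acmg_engine.data").joinpath("demo_genes.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        sym: GeneContext.model_validate({"symbol": sym, **fields})
        for sym, fields in raw.items()
    }


# ---------------------------------------------------------------------------
# Compact list encodings (shared by TSV and VCF INFO)
# ---------------------------------------------------------------------------

def encode_frequencies(records: Iterable[FrequencyRecord], item_sep: str = ",") -> str:
    return item_sep.join(
        f"{r.population}|{r.allele_count}|{r.allele_number}|{int(r.founder_effect)}"
        for r in records
    )


def decode_frequencies(text: str, item_sep: str = ",") -> list[FrequencyRecord]:
    out = []
    for item in filter(None, text.split(item_sep)):
        pop, ac, an, founder = item.split("|")
        out.append(
            FrequencyRecord(
                population=pop,
                allele_count=int(ac),
                allele_number=int(an),
                founder_effect=bool(int(founder)),
            )
        )
    return out


def encode_priors(priors: Iterable[PriorClassifiedVariant], item_sep: str = ",") -> str:
    return item_sep.join(
        f"{p.codon_index}|{p.alt_aa}|{int(p.protein_change_equivalent)}|"
        f"{p.classification.value}|{p.independent_report_count}"
        for p in priors
    )


def decode_priors(text: str, item_sep: str = ",") -> list[PriorClassifiedVariant]:
    out = []
    for item in filter(None, text.split(item_sep)):
        codon, alt_aa, equiv, cls, count = item.split("|")
        out.append(
            PriorClassifiedVariant(
                codon_index=int(codon),
                alt_aa=alt_aa,
                protein_change_equivalent=bool(int(equiv)),
                classification=PriorClassification(cls),
                independent_report_count=int(count),
            )
        )
    return out


_RECESSIVE_TOKEN = {
    "in_trans": (RecessivePhase.in_trans_with_PLP, False),
    "phase_unknown": (RecessivePhase.phase_unknown, False),
    "hom": (RecessivePhase.homozygous, False),
    "hom_consang": (RecessivePhase.homozygous, True),
}


def encode_recessive(obs: Iterable[RecessiveObservation], item_sep: str = ",") -> str:
    def token(o: RecessiveObservation) -> str:
        if o.phase == RecessivePhase.in_trans_with_PLP:
            return "in_trans"
        if o.phase == RecessivePhase.phase_unknown:
            return "phase_unknown"
        return "hom_consang" if o.consanguineous else "hom"

    return item_sep.join(token(o) for o in obs)


def decode_recessive(text: str, item_sep: str = ",") -> list[RecessiveObservation]:
    out = []
    for item in filter(None, text.split(item_sep)):
        phase, consang = _RECESSIVE_TOKEN[item]
        out.append(RecessiveObservation(phase=phase, consanguineous=consang))
    return out


def encode_denovo(obs: Iterable[DeNovoObservation], item_sep: str = ",") -> str:
    return item_sep.join(
        f"{'confirmed' if o.confirmed else 'assumed'}|{o.phenotype_match.value}" for o in obs
    )


def decode_denovo(text: str, item_sep: str = ",") -> list[DeNovoObservation]:
    out = []
    for item in filter(None, text.split(item_sep)):
        status, pheno = item.split("|")
        out.append(
            DeNovoObservation(
                confirmed=status == "confirmed", phenotype_match=PhenotypeMatch(pheno)
            )
        )
    return out


# ---------------------------------------------------------------------------
# Evidence readers
# ---------------------------------------------------------------------------

MISSING = "."

#: Flat TSV column schema; booleans are 0/1, missing values ``.``.
TSV_COLUMNS = [
    "id", "gene", "consequence", "codon_index", "ref_aa", "alt_aa",
    "indel_aa_length", "in_repeat_region", "nmd_predicted",
    "last_exon_or_50nt_rule", "affected_region_critical", "exon_skip_inframe",
    "cysteine_parity_change", "functional_splicing_aberrant",
    "frequencies", "prior_variants", "revel", "spliceai_delta", "gerp",
    "functional_direction", "functional_strength", "functional_proband_derived",
    "recessive_obs", "denovo_obs", "segregating_meioses",
    "nonsegregation_observed", "proband_count", "odds_ratio", "ci_low",
    "founder_variant", "vcep_pathogenic", "het", "hom", "hemi",
    "phenotype_specific_single_etiology", "comprehensive_test",
    "family_history_consistent", "pathognomonic_extra_evidence",
    "alternate_molecular_cause", "variant_noncontributory",
    "in_house_positive_genotype_no_phenotype",
]

_VARIANT_BOOL_FIELDS = (
    "in_repeat_region", "nmd_predicted", "last_exon_or_50nt_rule",
    "affected_region_critical", "exon_skip_inframe", "cysteine_parity_change",
    "functional_splicing_aberrant",
)
_CASE_BOOL_FIELDS = (
    "nonsegregation_observed", "founder_variant", "vcep_pathogenic",
    "phenotype_specific_single_etiology", "comprehensive_test",
    "family_history_consistent", "pathognomonic_extra_evidence",
    "alternate_molecular_cause", "variant_noncontributory",
    "in_house_positive_genotype_no_phenotype",
)


def _resolve_gene(
    value: Any, genes: Optional[dict[str, GeneContext]]
) -> GeneContext:
    if isinstance(value, GeneContext):
        return value
    if isinstance(value, dict):
        return GeneContext.model_validate(value)
    if isinstance(value, str):
        if not genes or value not in genes:
            raise ConfigurationError(
                f"gene symbol {value!r} not present in the gene-context config"
            )
        return genes[value]
    raise ConfigurationError(f"cannot resolve gene from {value!r}")


def record_from_dict(
    data: dict[str, Any], genes: Optional[dict[str, GeneContext]] = None
) -> EvidenceRecord:
    data = dict(data)
    data["gene"] = _resolve_gene(data.get("gene"), genes)
    return EvidenceRecord.model_validate(data)


def _row_to_record(
    row: dict[str, str], genes: dict[str, GeneContext], line: int
) -> EvidenceRecord:
    try:
        return _row_to_record_inner(row, genes, line)
    except Exception as exc:
        raise ValueError(f"line {line}: {exc}") from exc


def _row_to_record_inner(
    row: dict[str, str], genes: dict[str, GeneContext], line: int
) -> EvidenceRecord:
    def get(col: str) -> Optional[str]:
        val = row.get(col, MISSING)
        if val is None or val == MISSING or val == "":
            return None
        return str(val)

    variant: dict[str, Any] = {"consequence": get("consequence")}
    if get("codon_index"):
        variant["codon_index"] = int(get("codon_index"))
    for col in ("ref_aa", "alt_aa"):
        if get(col):
            variant[col] = get(col)
    if get("indel_aa_length"):
        variant["indel_aa_length"] = int(get("indel_aa_length"))
    for col in _VARIANT_BOOL_FIELDS:
        if get(col) is not None:
            variant[col] = bool(int(get(col)))

    insilico_scores: dict[str, Any] = {}
    for col in ("revel", "spliceai_delta", "gerp"):
        if get(col) is not None:
            insilico_scores[col] = float(get(col))

    functional: dict[str, Any] = {}
    if get("functional_direction"):
        functional["direction"] = get("functional_direction")
        functional["strength"] = get("functional_strength")
    if get("functional_proband_derived") is not None:
        functional["proband_derived"] = bool(int(get("functional_proband_derived")))

    case: dict[str, Any] = {}
    if get("recessive_obs"):
        case["recessive_obs"] = decode_recessive(get("recessive_obs"))
    if get("denovo_obs"):
        case["denovo_obs"] = decode_denovo(get("denovo_obs"))
    for col in ("segregating_meioses", "proband_count"):
        if get(col) is not None:
            case[col] = int(get(col))
    if get("odds_ratio") is not None and get("ci_low") is not None:
        case["case_control"] = CaseControlStudy(
            odds_ratio=float(get("odds_ratio")), ci_low=float(get("ci_low"))
        )
    carriers = {}
    for col in ("het", "hom", "hemi"):
        if get(col) is not None:
            carriers[col] = int(get(col))
    if carriers:
        case["healthy_carrier_counts"] = carriers
    for col in _CASE_BOOL_FIELDS:
        if get(col) is not None:
            case[col] = bool(int(get(col)))

    payload: dict[str, Any] = {
        "id": get("id") or f"row{line}",
        "gene": get("gene"),
        "variant": variant,
        "insilico": insilico_scores,
        "functional": functional,
        "case_data": case,
    }
    if get("frequencies"):
        payload["frequencies"] = decode_frequencies(get("frequencies"))
    if get("prior_variants"):
        payload["prior_variants"] = decode_priors(get("prior_variants"))
    return record_from_dict(payload, genes)


def record_to_tsv_row(record: EvidenceRecord) -> dict[str, str]:
    """Flatten an evidence record to the TSV column schema."""
    v, c = record.variant, record.case_data

    def b(val: Optional[bool]) -> str:
        return MISSING if val is None else str(int(val))

    def n(val: Optional[Union[int, float]]) -> str:
        return MISSING if val is None else f"{val:g}"

    row = {col: MISSING for col in TSV_COLUMNS}
    row.update(
        {
            "id": record.id,
            "gene": record.gene.symbol,
            "consequence": v.consequence.value,
            "codon_index": n(v.codon_index),
            "ref_aa": v.ref_aa or MISSING,
            "alt_aa": v.alt_aa or MISSING,
            "indel_aa_length": n(v.indel_aa_length),
            "frequencies": encode_frequencies(record.frequencies) or MISSING,
            "prior_variants": encode_priors(record.prior_variants) or MISSING,
            "revel": n(record.insilico.revel),
            "spliceai_delta": n(record.insilico.spliceai_delta),
            "gerp": n(record.insilico.gerp),
            "recessive_obs": encode_recessive(c.recessive_obs) or MISSING,
            "denovo_obs": encode_denovo(c.denovo_obs) or MISSING,
            "segregating_meioses": n(c.segregating_meioses),
            "proband_count": n(c.proband_count),
            "odds_ratio": n(c.case_control.odds_ratio) if c.case_control else MISSING,
            "ci_low": n(c.case_control.ci_low) if c.case_control else MISSING,
            "het": n(c.healthy_carrier_counts.het),
            "hom": n(c.healthy_carrier_counts.hom),
            "hemi": n(c.healthy_carrier_counts.hemi),
        }
    )
    for colset, obj in ((_VARIANT_BOOL_FIELDS, v), (_CASE_BOOL_FIELDS, c)):
        for col in colset:
            row[col] = b(getattr(obj, col))
    func = record.functional
    if func.direction.value != "none":
        row["functional_direction"] = func.direction.value
        row["functional_strength"] = func.strength.value
    row["functional_proband_derived"] = b(func.proband_derived)
    return row


def write_evidence_tsv(records: list[EvidenceRecord], path: Union[str, Path]) -> None:
    rows = [record_to_tsv_row(r) for r in records]
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_evidence(
    path: Union[str, Path],
    genes: Optional[dict[str, GeneContext]] = None,
) -> list[EvidenceRecord]:
    """Read evidence records from JSON, TSV or VCF (by extension).

    JSON may hold one record, a list, or ``{"records": [...]}``; gene
    fields may be inline objects or symbols resolved against ``genes``.
    Malformed records raise with line/field diagnostics.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        raw = json.loads(path.read_text())
        if isinstance(raw, dict) and "records" in raw:
            raw = raw["records"]
        if isinstance(raw, dict):
            raw = [raw]
        return [record_from_dict(item, genes) for item in raw]
    if suffix in (".tsv", ".txt"):
        if genes is None:
            raise ConfigurationError("TSV evidence requires a gene-context config")
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return [
            _row_to_record(row, genes, line)
            for line, row in enumerate(df.to_dict(orient="records"), start=2)
        ]
    if suffix == ".vcf":
        if genes is None:
            raise ConfigurationError("VCF evidence requires a gene-context config")
        return read_evidence_vcf(path, genes)
    raise ConfigurationError(f"unsupported evidence format: {path.name}")


#: VCF INFO keys mirror the TSV columns, uppercased; list-valued fields
#: use ``&`` as the item separator.  Booleans are INFO flags.
VCF_ITEM_SEP = "&"
_VCF_STRING_KEYS = {
    "CONSEQUENCE": "consequence",
    "REF_AA": "ref_aa",
    "ALT_AA": "alt_aa",
}


def read_evidence_vcf(
    path: Union[str, Path], genes: dict[str, GeneContext]
) -> list[EvidenceRecord]:
    """Read a minimal annotated VCF whose INFO fields carry the evidence."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            info = dict(rec.info)

            def get(key: str) -> Optional[str]:
                val = info.get(key)
                if val is None:
                    return None
                if isinstance(val, tuple):
                    val = val[0]
                return str(val)

            row: dict[str, str] = {col: MISSING for col in TSV_COLUMNS}
            row["id"] = rec.id or f"vcf{i}"
            row["gene"] = get("GENE") or MISSING
            for key, col in _VCF_STRING_KEYS.items():
                if get(key) is not None:
                    row[col] = get(key)
            for col in (
                "codon_index", "indel_aa_length", "revel", "spliceai_delta",
                "gerp", "segregating_meioses", "proband_count", "odds_ratio",
                "ci_low", "het", "hom", "hemi", "functional_direction",
                "functional_strength",
            ):
                val = get(col.upper())
                if val is not None:
                    row[col] = val
            for col in _VARIANT_BOOL_FIELDS + _CASE_BOOL_FIELDS + (
                "functional_proband_derived",
            ):
                key = col.upper()
                if key in info:
                    row[col] = "1" if info[key] in (True, None, "1", 1) else "0"
                elif col == "nmd_predicted":
                    row[col] = MISSING
            for col in ("frequencies", "prior_variants", "recessive_obs", "denovo_obs"):
                val = get(col.upper())
                if val is not None:
                    row[col] = val.replace(VCF_ITEM_SEP, ",")
            out.append(_row_to_record(row, genes, i))
    return out


# ---------------------------------------------------------------------------
# Per-variant pipeline
# ---------------------------------------------------------------------------

def evaluate_criteria(
    record: EvidenceRecord, config: Optional[RunConfig] = None
) -> list[CriterionCall]:
    """Run every criterion module over one record (28 audit entries)."""
    if config is None:
        config = RunConfig()
    gene, v = record.gene, record.variant
    calls: dict[Criterion, CriterionCall] = {}

    def add(call: Optional[CriterionCall]) -> None:
        if call is not None:
            calls[call.criterion] = call

    freq_call = population.evaluate_frequency(record.frequencies, gene)
    add(freq_call)
    pm2 = (
        freq_call
        if freq_call is not None
        and freq_call.applied
        and freq_call.criterion == Criterion.PM2
        else None
    )

    add(molecular.evaluate_pvs1(v, gene, table=config.pvs1_table))
    add(molecular.evaluate_ps1_pm5(v, record.prior_variants, record.insilico))
    add(molecular.evaluate_pm1(v, gene))
    add(molecular.evaluate_pm4(v, pm2))
    add(molecular.evaluate_pp2(v, gene))
    bp7 = molecular.evaluate_bp7(v, record.insilico)
    add(bp7)
    for call in molecular.unapplied_bp1_bp3():
        calls.setdefault(call.criterion, call)

    _, pm3_call = case_level.score_pm3(record.case_data.recessive_obs, gene.inheritance)
    add(pm3_call)
    dn = case_level.score_de_novo(record.case_data.denovo_obs)
    add(dn.ps2_call)
    add(dn.pm6_call)
    add(case_level.score_pp1(record.case_data.segregating_meioses, gene.inheritance))
    add(case_level.evaluate_ps4(record.case_data, gene, pm2))
    add(case_level.evaluate_bs2(record.case_data, gene))
    add(case_level.evaluate_bs4(record.case_data, gene))
    add(case_level.evaluate_pp4(record.case_data, pm2))
    add(case_level.evaluate_bp5(record.case_data, gene))
    calls.setdefault(Criterion.BP2, case_level.unapplied_bp2())

    add(insilico.evaluate_pp3_bp4(v, record.insilico, gene, bp7_call=bp7))
    add(insilico.evaluate_ps3_bs3(record.functional))
    for call in insilico.discontinued_criteria():
        calls.setdefault(call.criterion, call)

    # curated per-variant overrides replace the engine's own entry
    for override in record.curated_overrides:
        calls[override.criterion] = override

    audit = []
    for criterion in ALL_CRITERIA:
        audit.append(
            calls.get(criterion, unapplied_call(criterion, "no evidence evaluated"))
        )
    return audit


def classify_record(
    record: EvidenceRecord, config: Optional[RunConfig] = None
) -> Classification:
    """Classify a single evidence record end to end."""
    if config is None:
        config = RunConfig()
    outcome = gate_gene(record.gene)
    if outcome == GateOutcome.vcep_delegate:
        return Classification(
            record_id=record.id,
            status=RecordStatus.vcep_delegate,
            prior=config.prior,
            message=f"gene {record.gene.symbol} is VCEP-curated; general rules do not apply",
        )
    if outcome == GateOutcome.not_classifiable:
        return Classification(
            record_id=record.id,
            status=RecordStatus.not_classifiable,
            prior=config.prior,
            message=(
                f"gene {record.gene.symbol} clinical validity "
                f"{record.gene.clinical_validity.value!r} is below 'limited'"
            ),
        )
    audit = evaluate_criteria(record, config)
    return classify_calls(
        record.id,
        audit,
        prior=config.prior,
        caution_cap=config.caution_cap,
        ba1_points=config.ba1_points,
        boundaries=config.boundaries,
    )


def classify_variants(
    records: list[EvidenceRecord], config: Optional[RunConfig] = None
) -> list[Classification]:
    """Classify a batch; validation errors mark the record, not the batch."""
    if config is None:
        config = RunConfig()
    out = []
    for record in records:
        try:
            out.append(classify_record(record, config))
        except Exception as exc:  # propagate per record without aborting
            logger.error("record %s failed: %s", record.id, exc)
            out.append(
                Classification(
                    record_id=record.id,
                    status=RecordStatus.error,
                    prior=config.prior,
                    message=str(exc),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def classification_to_dict(c: Classification) -> dict[str, Any]:
    return {
        "record_id": c.record_id,
        "status": c.status.value,
        "tier": c.tier.value if c.tier else None,
        "matched_rule": c.matched_rule,
        "matched_rules": c.matched_rules,
        "post_p": round(c.post_p, 3) if c.post_p is not None else None,
        "posterior_tier": c.posterior_tier.value if c.posterior_tier else None,
        "prior": c.prior,
        "points": c.points,
        "applied": c.applied_labels(),
        "audit": [
            {
                "criterion": call.criterion.value,
                "strength": call.strength.value if call.strength else None,
                "direction": call.direction.value,
                "applied": call.applied,
                "rationale": call.rationale,
                "score": call.score,
            }
            for call in c.audit
        ],
        "message": c.message,
    }


SUMMARY_COLUMNS = [
    "record_id", "status", "tier", "matched_rule", "post_p", "posterior_tier",
    "points", "applied",
]


def write_report(
    classifications: list[Classification],
    out_prefix: Union[str, Path],
    output_format: str = "json",
) -> list[Path]:
    """Write the JSON audit report and/or the TSV summary.

    Output is deterministic: repeated runs on identical input and
    configuration produce byte-identical files.
    """
    out_prefix = Path(out_prefix)
    written = []
    if output_format in ("json", "both"):
        path = out_prefix.with_suffix(".json")
        payload = [classification_to_dict(c) for c in classifications]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)
    if output_format in ("tsv", "both"):
        path = out_prefix.with_suffix(".tsv")
        rows = []
        for c in classifications:
            d = classification_to_dict(c)
            d["applied"] = ",".join(d["applied"]) or MISSING
            rows.append({k: d[k] if d[k] is not None else MISSING for k in SUMMARY_COLUMNS})
        pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)
        written.append(path)
    if not written:
        raise ConfigurationError(f"unknown output format {output_format!r}")
    return written
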