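"""Domain types and readers/writers for candidate drug-target evidence.

A candidate target is a locus with four strands of annotation evidence:

* hits against three tiers of drug-reference databases (ChEMBL-style
  literature flags, DrugBank-style approved/clinical hits, TTD-style
  successful-target/compound hits) plus lead-compound and drug-domain
  indicators,
* a protein-family label (GPCR, kinase, ion channel, ...),
* an expression profile over seven tissues in FPKM units, and
* an essentiality flag (lethal phenotype in the mouse ortholog knockout).

All evidence arrives precomputed in tabular form; this module only
validates and moves it. Two TSV dialects are supported: ``fpkm`` carries
seven numeric tissue columns, while ``codes`` carries a comma-joined list
of single-letter tissue codes meaning "FPKM above threshold in these
tissues" (the style used in published top-target tables).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Tissue",
    "Family",
    "ExpressionProfile",
    "DrugEvidence",
    "CandidateTarget",
    "WeightConfig",
    "ValidationError",
    "FormatError",
    "read_candidates",
    "write_candidates",
    "read_weights",
    "write_scored",
    "read_scored",
]

# FPKM value assigned to tissues listed in the "codes" dialect; any value
# above the threshold is score-equivalent, 11 is simply documentation-friendly.
CODES_SENTINEL_FPKM = 11.0


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


class FormatError(ValueError):
    """A file does not match the declared dialect (e.g. missing columns)."""


class Tissue(enum.Enum):
    """The seven surveyed tissues, with their single-letter codes."""

    HEART = "H"
    LIVER = "L"
    BRAIN = "B"
    KIDNEY = "K"
    TESTIS = "T"
    OVARY = "O"
    PANCREAS = "P"

    @classmethod
    def from_code(cls, code: str) -> "Tissue":
        code = code.strip().upper()
        for t in cls:
            if t.value == code:
                return t
        raise ValidationError(f"unknown tissue code {code!r}")

    @property
    def code(self) -> str:
        return self.value


TISSUE_ORDER: tuple[Tissue, ...] = tuple(Tissue)


class Family(enum.Enum):
    """Druggable protein family of a candidate."""

    GPCR = "gpcr"
    KINASE = "kinase"
    ION_CHANNEL = "ion_channel"
    IMMUNE = "immune"
    NEUROPEPTIDE = "neuropeptide"
    PROTEASE = "protease"
    NUCLEAR_RECEPTOR = "nuclear_receptor"
    OTHER = "other"


@dataclass(frozen=True)
class ExpressionProfile:
    """FPKM per tissue; all seven tissues always present, values >= 0."""

    fpkm: Mapping[Tissue, float]

    def __post_init__(self) -> None:
        filled = {t: float(self.fpkm.get(t, 0.0)) for t in Tissue}
        for t, v in filled.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"FPKM for {t.name} must be finite and >= 0, got {v}")
        object.__setattr__(self, "fpkm", filled)

    def tissues_above(self, threshold: float) -> tuple[Tissue, ...]:
        """Tissues with FPKM strictly above ``threshold``, in canonical order."""
        return tuple(t for t in TISSUE_ORDER if self.fpkm[t] > threshold)

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "ExpressionProfile":
        """Build a thresholded profile from single-letter tissue codes.

        Listed tissues receive a sentinel FPKM above the default threshold;
        unlisted tissues receive 0.
        """
        listed = {Tissue.from_code(c) for c in codes if c.strip()}
        return cls({t: (CODES_SENTINEL_FPKM if t in listed else 0.0) for t in Tissue})

    @classmethod
    def empty(cls) -> "ExpressionProfile":
        return cls({t: 0.0 for t in Tissue})


@dataclass(frozen=True)
class DrugEvidence:
    """Per-candidate hits/flags against the three drug-reference tiers.

    ``drugbank_approved_hits``/``drugbank_experimental_hits`` are the Ia/Ie
    hit counts against approved and experimental drug lists;
    ``ttd_successful_hits``/``ttd_compound_hits`` are the Is/Ic counts
    against successful targets and compound-only targets.
    """

    chembl_hit: bool = False
    chembl_druggable: bool = False
    chembl_tractable: bool = False
    drugbank_approved_hits: int = 0
    drugbank_experimental_hits: int = 0
    drugbank_clinical_only: bool = False
    ttd_successful_hits: int = 0
    ttd_compound_hits: int = 0
    lead_compound: bool = False
    drug_domain: bool = False

    def __post_init__(self) -> None:
        for name in (
            "drugbank_approved_hits",
            "drugbank_experimental_hits",
            "ttd_successful_hits",
            "ttd_compound_hits",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"{name} must be a count >= 0, got {v!r}")
        if self.drugbank_clinical_only and self.drugbank_approved_hits > 0:
            raise ValidationError(
                "drugbank_clinical_only means no approved DrugBank target; "
                f"got {self.drugbank_approved_hits} approved hits"
            )


@dataclass(frozen=True)
class CandidateTarget:
    """One candidate locus with its annotation evidence.

    ``precomputed_drug_score`` optionally carries an externally supplied
    drug score (e.g. from a published table whose raw evidence rows are not
    available); when present the scoring engine uses it instead of
    recomputing from ``evidence``.
    """

    gene_id: str
    annotation: str = ""
    n_isoforms: int = 1
    family: Family = Family.OTHER
    evidence: DrugEvidence = field(default_factory=DrugEvidence)
    expression: ExpressionProfile = field(default_factory=ExpressionProfile.empty)
    essential: bool = False
    precomputed_drug_score: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not isinstance(self.n_isoforms, int) or self.n_isoforms < 1:
            raise ValidationError(f"n_isoforms must be >= 1, got {self.n_isoforms!r}")
        if self.precomputed_drug_score is not None and self.precomputed_drug_score < 0:
            raise ValidationError("precomputed_drug_score must be >= 0")


@dataclass(frozen=True)
class WeightConfig:
    """Criterion weights of the ranking scheme; defaults are the published ones.

    All weights are in score units and must be non-negative.
    ``fpkm_threshold`` is in FPKM units; expression contributes
    ``w_fpkm_per_tissue`` for every tissue with FPKM strictly above it.
    ``w_drugbank_experimental`` (the Ie term) defaults to 0: experimental-only
    DrugBank hits carry no weight in the published scheme but the knob is kept
    for completeness. ``count_weighted`` switches the DrugBank/TTD tiers from
    indicator (hit count > 0) to count-multiplied contributions.
    """

    w_fpkm_per_tissue: float = 0.1
    w_essential: float = 0.1
    w_chembl_hit: float = 0.25
    w_chembl_druggable: float = 0.75
    w_chembl_tractable: float = 0.25
    w_drugbank_approved: float = 1.0
    w_drugbank_clinical: float = 0.25
    w_ttd_successful: float = 1.0
    w_ttd_compound: float = 0.25
    w_lead_compound: float = 1.0
    w_gpcr_or_kinase: float = 1.0
    w_drug_domain_no_lead: float = 0.2
    w_chembl: float = 1.0
    w_drugbank_experimental: float = 0.0
    fpkm_threshold: float = 10.0
    count_weighted: bool = False

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name == "count_weighted":
                continue
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"weight {name} must be finite and >= 0, got {v}")

    def replace(self, **overrides) -> "WeightConfig":
        d = asdict(self)
        unknown = set(overrides) - set(d)
        if unknown:
            raise ValidationError(f"unknown weight field(s): {sorted(unknown)}")
        d.update(overrides)
        return WeightConfig(**d)


# ---------------------------------------------------------------------------
# Tabular I/O

_BASE_COLUMNS = ["gene_id", "annotation", "n_isoforms", "family", "essential"]
_EVIDENCE_COLUMNS = [
    "chembl_hit",
    "chembl_druggable",
    "chembl_tractable",
    "drugbank_approved_hits",
    "drugbank_experimental_hits",
    "drugbank_clinical_only",
    "ttd_successful_hits",
    "ttd_compound_hits",
    "lead_compound",
    "drug_domain",
]
_TISSUE_COLUMNS = [t.code for t in TISSUE_ORDER]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(value, row: int, col: str) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"row {row}: cannot parse {col}={value!r} as a boolean")


def _parse_count(value, row: int, col: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
        return 0
    try:
        n = int(float(value))
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: cannot parse {col}={value!r} as a count") from None
    return n


def _evidence_from_row(row: Mapping, rownum: int) -> DrugEvidence:
    kwargs = {}
    for col in _EVIDENCE_COLUMNS:
        if col not in row:
            continue
        if col.endswith("_hits"):
            kwargs[col] = _parse_count(row[col], rownum, col)
        else:
            kwargs[col] = _parse_bool(row[col], rownum, col)
    try:
        return DrugEvidence(**kwargs)
    except ValidationError as e:
        raise ValidationError(f"row {rownum}: {e}") from None


def _candidate_from_row(row: Mapping, rownum: int, dialect: str) -> CandidateTarget:
    family_raw = str(row.get("family", "other") or "other").strip().lower()
    try:
        family = Family(family_raw)
    except ValueError:
        raise ValidationError(f"row {rownum}: unknown family {family_raw!r}") from None

    if dialect == "fpkm":
        try:
            # blank cells are treated as unmeasured -> 0 FPKM
            expression = ExpressionProfile(
                {
                    t: (float(row[t.code]) if str(row[t.code]).strip() else 0.0)
                    for t in TISSUE_ORDER
                }
            )
        except (TypeError, ValueError) as e:
            raise ValidationError(f"row {rownum}: bad FPKM value ({e})") from None
    else:  # codes
        raw = row.get("tissue_expression", "")
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            raw = ""
        try:
            expression = ExpressionProfile.from_codes(str(raw).split(","))
        except ValidationError as e:
            raise ValidationError(f"row {rownum}: {e}") from None

    drug_score = None
    if "drug_score" in row and str(row["drug_score"]).strip() not in ("", "nan"):
        drug_score = float(row["drug_score"])

    try:
        return CandidateTarget(
            gene_id=str(row["gene_id"]).strip(),
            annotation=str(row.get("annotation", "") or ""),
            n_isoforms=_parse_count(row.get("n_isoforms", 1), rownum, "n_isoforms") or 1,
            family=family,
            evidence=_evidence_from_row(row, rownum),
            expression=expression,
            essential=_parse_bool(row.get("essential", False), rownum, "essential"),
            precomputed_drug_score=drug_score,
        )
    except ValidationError as e:
        msg = str(e)
        raise ValidationError(msg if msg.startswith(f"row {rownum}") else f"row {rownum}: {e}") from None


def read_candidates(path: str | Path, dialect: str = "fpkm") -> list[CandidateTarget]:
    """Read a candidate table from TSV (or a JSON mirror).

    Parameters
    ----------
    path
        TSV file with a header row, or a ``.json`` file holding a list of
        candidate records with the same field names.
    dialect
        ``"fpkm"`` — seven numeric tissue columns named by the single-letter
        codes H,L,B,K,T,O,P; ``"codes"`` — one ``tissue_expression`` column
        holding a comma-joined list of codes for tissues above the FPKM
        threshold.

    Raises
    ------
    FormatError
        if a required column is missing.
    ValidationError
        with row numbers, if any row violates a domain invariant or two rows
        share a ``gene_id``.
    """
    path = Path(path)
    if dialect not in ("fpkm", "codes"):
        raise FormatError(f"unknown dialect {dialect!r}; expected 'fpkm' or 'codes'")

    if path.suffix == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise FormatError("JSON candidate file must hold a list of records")
        rows = list(enumerate(records, start=1))
        columns = set(records[0]) if records else set()
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        columns = set(df.columns)
        rows = list(enumerate(df.to_dict("records"), start=1))

    required = {"gene_id"}
    if dialect == "fpkm":
        required |= set(_TISSUE_COLUMNS)
    else:
        required |= {"tissue_expression"}
    missing = required - columns if rows or columns else required - columns
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")

    candidates = [_candidate_from_row(row, rownum, dialect) for rownum, row in rows]

    seen: dict[str, int] = {}
    dups: list[str] = []
    for c in candidates:
        if c.gene_id in seen:
            dups.append(c.gene_id)
        seen.setdefault(c.gene_id, 1)
    if dups:
        raise ValidationError(f"duplicate gene_id(s): {sorted(set(dups))}")
    return candidates


def _candidate_to_record(c: CandidateTarget) -> dict:
    rec: dict = {
        "gene_id": c.gene_id,
        "annotation": c.annotation,
        "n_isoforms": c.n_isoforms,
        "family": c.family.value,
        "essential": c.essential,
    }
    rec.update({col: getattr(c.evidence, col) for col in _EVIDENCE_COLUMNS})
    rec.update({t.code: c.expression.fpkm[t] for t in TISSUE_ORDER})
    if c.precomputed_drug_score is not None:
        rec["drug_score"] = c.precomputed_drug_score
    return rec


def write_candidates(candidates: Sequence[CandidateTarget], path: str | Path) -> None:
    """Write candidates in the ``fpkm`` TSV dialect (or JSON for ``.json`` paths)."""
    path = Path(path)
    records = [_candidate_to_record(c) for c in candidates]
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1))
        return
    cols = _BASE_COLUMNS + _EVIDENCE_COLUMNS + _TISSUE_COLUMNS
    df = pd.DataFrame(records, columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path) -> WeightConfig:
    """Read a flat ``key: value`` weight-override file (YAML/JSON compatible)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise FormatError("weight config must be a flat mapping of field: value")
    return WeightConfig().replace(**data)


# ---------------------------------------------------------------------------
# Scored-table I/O (the ranked output surface)

_SCORED_COLUMNS = [
    "gene_id",
    "annotation",
    "n_isoforms",
    "tissues_above_threshold",
    "drug_score",
    "total_score",
    "rank",
]


def write_scored(targets: Sequence, path: str | Path, threshold: float = 10.0) -> None:
    """Write a ranked target table as TSV.

    Scores are printed with two decimal places (round-half-even); tissue
    codes list the tissues whose FPKM exceeds ``threshold``.
    """
    rows = []
    for st in targets:
        c = st.candidate
        rows.append(
            {
                "gene_id": c.gene_id,
                "annotation": c.annotation,
                "n_isoforms": c.n_isoforms,
                "tissues_above_threshold": ",".join(
                    t.code for t in c.expression.tissues_above(threshold)
                ),
                "drug_score": f"{st.drug_score:.2f}",
                "total_score": f"{st.total_score:.2f}",
                "rank": st.rank,
            }
        )
    pd.DataFrame(rows, columns=_SCORED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scored(path: str | Path) -> pd.DataFrame:
    """Read back a ranked target table written by :func:`write_scored`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"tissues_above_threshold": str})
    missing = set(_SCORED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    return df
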