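"""Mutation-cohort classification statistics for fibrillin-1.

Missense records from a mutation registry are split into disease cohorts by
exact keyword match on the disease label (neonatal-Marfan keywords take
precedence over the generic "MFS", which is a substring of them), assigned
to protein domains by inclusive residue range, and classified by functional
residue class: calcium-binding residue, disulfide-bond-forming cysteine
(bond 1 = C1–C3, bond 2 = C2–C4, bond 3 = C5–C6) or other. Cohort
percentages carry binomial standard errors √(p(1−p)/n) and cohorts are
compared with a 2×2 chi-squared test (no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataInconsistencyError, ValidationError
from .structure import DomainMap

__all__ = [
    "MutationRecord",
    "records_from_frame",
    "NMFS_KEYWORDS",
    "CMFS_KEYWORDS",
    "FilterResult",
    "filter_records",
    "assign_domain",
    "ResidueClassification",
    "classify_residue",
    "CohortSummary",
    "summarize_cohort",
    "ComparisonResult",
    "compare_cohorts",
    "chi2_2x2",
    "uniform_random_baseline",
    "NEONATAL_REGION",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Disease-label keywords defining the neonatal cohort (the second spelling
#: reproduces the registry's as-published keyword; the third accepts the
#: presumably intended spelling).
NMFS_KEYWORDS = ("neonatal MFS", "intantil MFS", "infantile MFS")

#: Disease-label keywords defining the classical cohort.
CMFS_KEYWORDS = ("Classical MFS", "MFS")

#: The neonatal region: cbEGF domains 11–18.
NEONATAL_REGION = tuple(f"cbEGF{i}" for i in range(11, 19))


@dataclass(frozen=True)
class MutationRecord:
    """One missense record: a substitution at a 1-based protein position."""

    record_id: str
    position: int
    wt_aa: str
    mut_aa: str
    disease: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        for aa, role in ((self.wt_aa, "wild-type"), (self.mut_aa, "substituted")):
            if aa not in VALID_AA:
                raise ValidationError(f"invalid {role} residue code {aa!r}")


def records_from_frame(df: pd.DataFrame) -> list[MutationRecord]:
    """Convert a records table (id, position, wt_aa, mut_aa, disease)."""
    required = {"id", "position", "wt_aa", "mut_aa", "disease"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"records table missing columns: {sorted(missing)}")
    return [
        MutationRecord(
            record_id=str(row.id),
            position=int(row.position),
            wt_aa=str(row.wt_aa),
            mut_aa=str(row.mut_aa),
            disease=str(row.disease),
        )
        for row in df.itertuples()
    ]


@dataclass(frozen=True)
class FilterResult:
    """Cohort partition of a record table: every record lands in exactly one bin."""

    nmfs: list
    cmfs: list
    excluded: list

    @property
    def n_included(self) -> int:
        return len(self.nmfs) + len(self.cmfs)

    @property
    def n_total(self) -> int:
        return self.n_included + len(self.excluded)


def filter_records(
    records,
    nmfs_keywords=NMFS_KEYWORDS,
    cmfs_keywords=CMFS_KEYWORDS,
) -> FilterResult:
    """Partition records into (nMFS, cMFS, excluded) by disease label.

    Matching is exact and case-sensitive against each keyword, with the
    neonatal keywords tested first — necessary because the generic "MFS"
    keyword is contained in "neonatal MFS". Unmatched labels are excluded.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    nmfs, cmfs, excluded = [], [], []
    for rec in records:
        if rec.disease in nmfs_keywords:
            nmfs.append(rec)
        elif rec.disease in cmfs_keywords:
            cmfs.append(rec)
        else:
            excluded.append(rec)
    return FilterResult(nmfs=nmfs, cmfs=cmfs, excluded=excluded)


def assign_domain(record: MutationRecord, dmap: DomainMap) -> tuple[str, str]:
    """(domain name, domain type) of the record's position; gaps are 'other'."""
    domain = dmap.domain_of(record.position)  # raises beyond protein length
    if domain is None:
        return ("linker", "other")
    return (domain.name, domain.domain_type)


@dataclass(frozen=True)
class ResidueClassification:
    """Functional class of a mutated residue."""

    category: str  # calcium_binding | cysteine | other
    bond: int | None = None  # 1, 2 or 3 when category == "cysteine"

    @property
    def label(self) -> str:
        if self.category == "cysteine":
            return f"cysteine_bond{self.bond}"
        return self.category


def classify_residue(record: MutationRecord, dmap: DomainMap) -> ResidueClassification:
    """Classify a record as calcium-binding, cysteine (with bond), or other.

    A cysteine record maps to the disulfide bond of the mutated cysteine's
    ordinal; mutating either partner counts toward that bond. A record
    claiming a cysteine wild type at a position the map does not annotate as
    cysteine is flagged as inconsistent data.
    """
    cys = dmap.cysteine_positions()
    if record.position in cys:
        _, _, bond = cys[record.position]
        return ResidueClassification(category="cysteine", bond=bond)
    if record.wt_aa == "C":
        domain = dmap.domain_of(record.position)
        if domain is not None and domain.cysteines:
            raise DataInconsistencyError(
                f"record {record.record_id}: wild-type C at position "
                f"{record.position} which {domain.name} does not annotate as cysteine"
            )
    if record.position in dmap.calcium_binding_positions():
        return ResidueClassification(category="calcium_binding")
    return ResidueClassification(category="other")


@dataclass(frozen=True)
class CohortSummary:
    """Classified cross-tabulation of one disease cohort.

    ``class_counts`` uses denominator ``n`` (all records); ``bond_counts``
    uses the cysteine-record count as denominator, matching how per-bond
    percentages are reported. Standard errors are binomial, √(p(1−p)/n).
    """

    name: str
    n: int
    class_counts: dict  # calcium_binding | cysteine | other -> count
    bond_counts: dict  # 1 | 2 | 3 -> count
    domain_type_counts: dict  # domain type -> count
    cbegf_domain_counts: dict = field(default_factory=dict)  # cbEGF name -> count

    def proportion(self, key) -> tuple[float, float, int, int]:
        """(p, SE, count, denominator) for a class name or bond number."""
        if isinstance(key, int):
            count = self.bond_counts.get(key, 0)
            denom = sum(self.bond_counts.values())
        elif key in self.class_counts:
            count = self.class_counts[key]
            denom = self.n
        elif key in self.domain_type_counts or key in (
            "EGF",
            "cbEGF",
            "TB",
            "hybrid",
            "other",
        ):
            count = self.domain_type_counts.get(key, 0)
            denom = self.n
        else:
            raise KeyError(key)
        if denom == 0:
            raise ValidationError(f"cohort {self.name} has empty denominator for {key!r}")
        p = count / denom
        se = float(np.sqrt(p * (1.0 - p) / denom))
        return p, se, count, denom

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in list(self.class_counts) + list(self.bond_counts):
            p, se, count, denom = self.proportion(key)
            rows.append(
                {
                    "cohort": self.name,
                    "class": key if isinstance(key, str) else f"bond{key}",
                    "count": count,
                    "denominator": denom,
                    "percent": 100.0 * p,
                    "se_percent": 100.0 * se,
                }
            )
        return pd.DataFrame(rows)


def summarize_cohort(records, dmap: DomainMap, name: str) -> CohortSummary:
    """Classify and cross-tabulate one cohort's records."""
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    class_counts = {"calcium_binding": 0, "cysteine": 0, "other": 0}
    bond_counts = {1: 0, 2: 0, 3: 0}
    domain_type_counts: dict = {}
    cbegf_domain_counts: dict = {}
    for rec in records:
        cls = classify_residue(rec, dmap)
        class_counts[cls.category] += 1
        if cls.bond is not None:
            bond_counts[cls.bond] += 1
        dname, dtype = assign_domain(rec, dmap)
        domain_type_counts[dtype] = domain_type_counts.get(dtype, 0) + 1
        if dtype == "cbEGF":
            cbegf_domain_counts[dname] = cbegf_domain_counts.get(dname, 0) + 1
    return CohortSummary(
        name=name,
        n=len(records),
        class_counts=class_counts,
        bond_counts=bond_counts,
        domain_type_counts=domain_type_counts,
        cbegf_domain_counts=cbegf_domain_counts,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """A 2×2 cohort comparison: proportions, chi-squared and p-value."""

    table: np.ndarray  # 2×2 counts
    chi2: float
    dof: int
    p_value: float
    proportion_a: float
    proportion_b: float


def chi2_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Chi-squared statistic and p-value of a 2×2 contingency table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError("table must be 2×2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValidationError("table entries must be non-negative integers")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValidationError("degenerate table: an expected count is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def compare_cohorts(
    summary_a: CohortSummary,
    summary_b: CohortSummary,
    key,
    yates: bool = False,
) -> ComparisonResult:
    """Chi-squared comparison of one class proportion between two cohorts.

    *key* is a residue-class name, a domain type, or a disulfide bond
    number (1–3; bond proportions are taken out of each cohort's cysteine
    records). No continuity correction by default; ``yates=True`` applies it.
    """
    p_a, _, k_a, n_a = summary_a.proportion(key)
    p_b, _, k_b, n_b = summary_b.proportion(key)
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=int)
    chi2, p = chi2_2x2(table, yates=yates)
    return ComparisonResult(
        table=table,
        chi2=chi2,
        dof=1,
        p_value=p,
        proportion_a=p_a,
        proportion_b=p_b,
    )


def uniform_random_baseline(
    dmap: DomainMap,
    n_draws: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected mutation percentage per domain type under a uniform model.

    The analytic expectation is simply each type's share of the protein
    sequence. With ``n_draws`` > 0 a Monte-Carlo draw of uniformly placed
    mutations is added (percent and binomial SE), which is what error bars
    on a "random" reference bar represent.
    """
    by_type = dmap.residues_by_type()
    total = dmap.protein_length
    rows = []
    mc_counts = None
    if n_draws > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
        positions = rng.integers(1, total + 1, size=n_draws)
        mc_counts = {t: 0 for t in by_type}
        boundaries = [(d.start, d.end, d.domain_type) for d in dmap.domains]
        for pos in positions:
            dtype = "other"
            for start, end, t in boundaries:
                if start <= pos <= end:
                    dtype = t
                    break
            mc_counts[dtype] = mc_counts.get(dtype, 0) + 1
    for dtype, n_res in by_type.items():
        expected = 100.0 * n_res / total
        row = {"domain_type": dtype, "expected_percent": expected}
        if mc_counts is not None:
            p_hat = mc_counts.get(dtype, 0) / n_draws
            row["mc_percent"] = 100.0 * p_hat
            row["mc_se_percent"] = 100.0 * float(
                np.sqrt(p_hat * (1 - p_hat) / n_draws)
            )
        rows.append(row)
    return pd.DataFrame(rows)
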