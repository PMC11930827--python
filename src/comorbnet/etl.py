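"""Cleaning, recoding and matrix construction for ICD-10 visit records.

Raw input is one row per diagnosis event: ``patient_id, sex, age, icd10``.
The pipeline deduplicates repeat visits for the same (patient, disease) pair,
merges related ICD-10 codes into panel labels, applies the exclusion cascade
(age window, malformed codes, non-chronic diseases, low-prevalence diseases,
single-disease patients), builds the disease panel around the most prevalent
index diseases, and pivots to a binary patient x disease matrix suitable for
Ising network estimation.

Every stage logs how many records entered, survived and were dropped; the
resulting :class:`ExclusionReport` is the machine-readable analogue of a
records-exclusion flowchart.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RecodeRule",
    "DiseasePanel",
    "ComorbidityMatrix",
    "ExclusionReport",
    "ConfigError",
    "PipelineError",
    "validate_icd10",
    "read_records",
    "load_panel",
    "default_panel",
    "deduplicate",
    "apply_recoding",
    "apply_exclusions",
    "build_panel",
    "build_matrix",
    "sample_by_sex",
    "run_etl",
]

RECORD_COLUMNS = ["patient_id", "sex", "age", "code"]

#: one uppercase letter, two digits, optional dot plus 1-3 digits; no padding
_ICD10_RE = re.compile(r"[A-Z][0-9]{2}(\.[0-9]{1,3})?")


class ConfigError(ValueError):
    """Invalid recode-rule or panel configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage produced an unusable (e.g. empty) result."""


def validate_icd10(code: object) -> bool:
    """Check whether ``code`` is a well-formed ICD-10 diagnosis code.

    Accepts the canonical shape ``L dd`` optionally followed by ``.d``,
    ``.dd`` or ``.ddd`` (e.g. ``A01.001``).  Anything else — empty strings,
    lowercase letters, leading/trailing whitespace, stray characters — is
    rejected.  Total function: never raises.
    """
    if not isinstance(code, str):
        return False
    return _ICD10_RE.fullmatch(code) is not None


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class RecodeRule:
    """Maps a set of raw ICD-10 codes/prefixes onto one panel label."""

    new_code: str
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ConfigError(f"rule {self.new_code!r} has no sources")


@dataclass(frozen=True)
class PanelEntry:
    code: str
    name: str
    top5: bool = False


@dataclass
class DiseasePanel:
    """Ordered disease panel (recoded labels) with display names and top-5 flags."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ConfigError("duplicate codes in disease panel")

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    @property
    def top5(self) -> list[str]:
        return [e.code for e in self.entries if e.top5]

    @property
    def names(self) -> dict[str, str]:
        return {e.code: e.name for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in set(self.codes)


def _check_disjoint(rules: Sequence[RecodeRule]) -> None:
    """Sources of distinct rules must not overlap, including by prefix."""
    owner: dict[str, str] = {}
    for rule in rules:
        for src in rule.sources:
            if src in owner and owner[src] != rule.new_code:
                raise ConfigError(
                    f"source {src!r} claimed by both {owner[src]!r} and {rule.new_code!r}"
                )
            owner[src] = rule.new_code
    sources = sorted(owner)
    for a, b in zip(sources, sources[1:]):
        # a sorted prefix pair is adjacent; same-rule nesting is allowed
        if b.startswith(a) and owner[a] != owner[b]:
            raise ConfigError(
                f"source {a!r} ({owner[a]}) is a prefix of {b!r} ({owner[b]})"
            )


def load_panel(path: str | Path | None = None) -> tuple[DiseasePanel, list[RecodeRule]]:
    """Load a panel + recode-rule YAML file (default: the shipped 38-code panel)."""
    if path is None:
        text = resources.files("comorbnet.data").joinpath("panel38.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    entries, rules = [], []
    for item in raw["panel"]:
        entries.append(
            PanelEntry(str(item["code"]), str(item.get("name", item["code"])),
                       bool(item.get("top5", False)))
        )
        rules.append(RecodeRule(str(item["code"]),
                                tuple(str(s) for s in item["sources"])))
    _check_disjoint(rules)
    return DiseasePanel(entries), rules


def default_panel() -> tuple[DiseasePanel, list[RecodeRule]]:
    return load_panel(None)


# ---------------------------------------------------------------------------
# record I/O


def read_records(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited visit-record file (CSV/TSV, transparently gzipped).

    Expects header columns ``patient_id, sex, age, icd10`` (the diagnosis
    column is renamed to ``code`` internally).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype={"patient_id": str}, keep_default_na=False)
    if "icd10" in df.columns:
        df = df.rename(columns={"icd10": "code"})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"record file {path} lacks columns: {missing}")
    df["code"] = df["code"].astype(str)
    df["age"] = df["age"].astype(int)
    return df[RECORD_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# exclusion bookkeeping


@dataclass
class ExclusionReport:
    """Per-stage record accounting: (stage, records in, records out, dropped)."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append((name, n_in, n_out, n_in - n_out))

    def dropped(self, name: str) -> int:
        for stage, _, _, d in self.stages:
            if stage == name:
                return d
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "records_in", "records_out", "records_dropped"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        lines = ["exclusion report:"]
        for stage, n_in, n_out, d in self.stages:
            lines.append(f"  {stage:<18} in={n_in:>9}  out={n_out:>9}  dropped={d:>9}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cleaning stages


def filter_age(records: pd.DataFrame, age_range: tuple[int, int] = (60, 99),
               report: ExclusionReport | None = None) -> pd.DataFrame:
    """Keep records whose age lies in the closed study window."""
    lo, hi = age_range
    out = records[(records["age"] >= lo) & (records["age"] <= hi)]
    if report is not None:
        report.add("age-window", len(records), len(out))
    return out.reset_index(drop=True)


def deduplicate(records: pd.DataFrame,
                report: ExclusionReport | None = None) -> pd.DataFrame:
    """Collapse repeat visits: one record per (patient_id, code), first kept."""
    out = records.drop_duplicates(subset=["patient_id", "code"], keep="first")
    if report is not None:
        report.add("deduplicate", len(records), len(out))
    return out.reset_index(drop=True)


def apply_recoding(records: pd.DataFrame, rules: Sequence[RecodeRule],
                   report: ExclusionReport | None = None) -> pd.DataFrame:
    """Rewrite raw ICD-10 codes to panel labels and re-deduplicate.

    A record matches a rule when its code equals a source or extends a source
    prefix (``I25`` matches ``I25.1``); the longest matching source wins.
    Only well-formed ICD-10 codes are eligible for rewriting, so malformed
    strings can never be recoded into a valid label.  Two raw codes of one
    patient that map to the same label collapse into a single record.
    """
    _check_disjoint(rules)
    matchers = [(src, rule.new_code) for rule in rules for src in rule.sources]
    matchers.sort(key=lambda m: len(m[0]), reverse=True)

    def recode_one(code: str) -> str:
        if not validate_icd10(code):
            return code
        for src, new in matchers:
            if code == src or code.startswith(src):
                return new
        return code

    mapping = {c: recode_one(c) for c in records["code"].unique()}
    out = records.assign(code=records["code"].map(mapping))
    out = out.drop_duplicates(subset=["patient_id", "code"], keep="first")
    if report is not None:
        report.add("recode-merge", len(records), len(out))
    return out.reset_index(drop=True)


def apply_exclusions(
    records: pd.DataFrame,
    chronic_allowlist: Iterable[str],
    min_prevalence: float = 0.01,
    *,
    recognized_codes: Iterable[str] | None = None,
    prevalence_denominator: str = "patients",
    report: ExclusionReport | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the exclusion cascade on recoded records.

    Stages, in order:

    1. ``invalid-code`` — drop codes that neither satisfy ICD-10 rules nor
       appear in ``recognized_codes`` (defaults to the allowlist, so recoded
       labels such as ``II2520`` survive);
    2. ``non-chronic``   — drop diseases outside ``chronic_allowlist``;
    3. ``low-prevalence``— drop diseases whose prevalence, computed once on
       the population entering this stage, falls below ``min_prevalence``.
       The denominator is distinct patients by default
       (``prevalence_denominator="records"`` switches to record count);
    4. ``single-disease``— drop patients left with exactly one disease.
    """
    allow = set(chronic_allowlist)
    recognized = allow if recognized_codes is None else set(recognized_codes)
    if report is None:
        report = ExclusionReport()

    ok = records["code"].map(lambda c: validate_icd10(c) or c in recognized)
    step = records[ok]
    report.add("invalid-code", len(records), len(step))

    nxt = step[step["code"].isin(allow)]
    report.add("non-chronic", len(step), len(nxt))
    step = nxt

    if prevalence_denominator == "patients":
        denom = step["patient_id"].nunique()
    elif prevalence_denominator == "records":
        denom = len(step)
    else:
        raise ConfigError(f"unknown prevalence denominator {prevalence_denominator!r}")
    if denom > 0:
        carriers = step.groupby("code")["patient_id"].nunique()
        keep_codes = set(carriers[carriers / denom >= min_prevalence].index)
        nxt = step[step["code"].isin(keep_codes)]
    else:
        nxt = step
    report.add("low-prevalence", len(step), len(nxt))
    step = nxt

    n_dis = step.groupby("patient_id")["code"].transform("nunique")
    nxt = step[n_dis >= 2]
    report.add("single-disease", len(step), len(nxt))
    step = nxt.reset_index(drop=True)

    if step.empty:
        raise PipelineError("exclusion cascade removed every record")
    return step, report


# ---------------------------------------------------------------------------
# panel construction


def _patient_sets(records: pd.DataFrame) -> dict[str, set[str]]:
    return {code: set(grp) for code, grp in records.groupby("code")["patient_id"]}


def build_panel(
    records: pd.DataFrame,
    n_top: int = 5,
    n_comorbid: int = 40,
    *,
    rate: str = "conditional",
    names: Mapping[str, str] | None = None,
) -> DiseasePanel:
    """Build the analysis panel around the most prevalent index diseases.

    The ``n_top`` most prevalent diseases seed the panel; for each, every
    other disease is ranked by its comorbidity rate with the index disease
    and the top ``n_comorbid`` are pooled.  The panel is the de-duplicated
    union, ordered by overall prevalence (descending, ties lexicographic).

    ``rate="conditional"`` uses P(other | index) = co-carriers / index
    carriers; ``rate="jaccard"`` uses |A∩B| / |A∪B|.
    """
    sets = _patient_sets(records)
    if len(sets) < n_top:
        raise PipelineError(f"only {len(sets)} diseases present, need n_top={n_top}")
    by_prev = sorted(sets, key=lambda c: (-len(sets[c]), c))
    top = by_prev[:n_top]

    selected: set[str] = set(top)
    for index_code in top:
        a = sets[index_code]
        scored = []
        for other, b in sets.items():
            if other == index_code:
                continue
            inter = len(a & b)
            r = inter / len(a) if rate == "conditional" else inter / len(a | b)
            scored.append((-r, other))
        scored.sort()
        selected.update(code for _, code in scored[:n_comorbid])

    ordered = [c for c in by_prev if c in selected]
    names = names or {}
    entries = [PanelEntry(c, names.get(c, c), c in set(top)) for c in ordered]
    return DiseasePanel(entries)


# ---------------------------------------------------------------------------
# matrix construction


@dataclass
class ComorbidityMatrix:
    """Binary patients x diseases matrix with a per-patient sex label.

    ``data`` is indexed by patient id with one 0/1 column per panel code, in
    panel order; ``sex`` is aligned to the same index (may be absent for
    purely synthetic Gibbs samples).
    """

    data: pd.DataFrame
    sex: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("comorbidity matrix entries must be 0/1")
        if self.sex is not None and not self.sex.index.equals(self.data.index):
            self.sex = self.sex.reindex(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)

    @property
    def codes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.sex is not None:
            out.insert(0, "sex", self.sex)
        out.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ComorbidityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        sex = None
        if "sex" in df.columns:
            sex = df.pop("sex")
        return cls(df.astype(np.int8), sex)

    def to_coo_tsv(self, path: str | Path) -> None:
        """Sparse coordinate triplets (patient_id, code, 1)."""
        rows, cols = np.nonzero(self.values)
        pd.DataFrame({
            "patient_id": self.data.index[rows],
            "code": self.data.columns[cols],
            "value": 1,
        }).to_csv(path, sep="\t", index=False)


def build_matrix(records: pd.DataFrame, panel: DiseasePanel,
                 *, drop_empty_rows: bool = False,
                 drop_single_rows: bool = False) -> ComorbidityMatrix:
    """Pivot filtered records into the binary comorbidity matrix.

    One row per patient (first-occurrence order), one column per panel code.
    Patients whose diseases all fall outside the panel yield all-zero rows;
    by default they are kept, the matrix reflecting panel restriction only.
    """
    patients = records["patient_id"].drop_duplicates()
    codes = panel.codes
    in_panel = records[records["code"].isin(codes)]
    index = pd.Index(patients, name="patient_id")
    cols = pd.Index(codes)
    arr = np.zeros((len(index), len(cols)), dtype=np.int8)
    if len(in_panel):
        arr[index.get_indexer(in_panel["patient_id"]),
            cols.get_indexer(in_panel["code"])] = 1
    mat = pd.DataFrame(arr, index=index, columns=cols)
    sex = None
    if "sex" in records.columns:
        sex = records.drop_duplicates("patient_id").set_index("patient_id")["sex"]
        sex = sex.reindex(mat.index)
    row_sums = mat.sum(axis=1)
    keep = pd.Series(True, index=mat.index)
    if drop_empty_rows:
        keep &= row_sums > 0
    if drop_single_rows:
        keep &= row_sums != 1
    mat = mat[keep]
    if sex is not None:
        sex = sex[keep]
    return ComorbidityMatrix(mat, sex)


def sample_by_sex(matrix: ComorbidityMatrix, n_per_sex: int,
                  seed: int) -> ComorbidityMatrix:
    """Sample ``n_per_sex`` rows uniformly without replacement per sex stratum.

    A stratum smaller than ``n_per_sex`` is returned whole, with a warning.
    Deterministic for a fixed seed; row order follows the original matrix.
    """
    if matrix.sex is None:
        raise ValueError("matrix has no sex labels to stratify on")
    rng = np.random.default_rng(seed)
    take = np.zeros(matrix.n_patients, dtype=bool)
    sex_arr = matrix.sex.to_numpy()
    for stratum in sorted(pd.unique(sex_arr)):
        idx = np.flatnonzero(sex_arr == stratum)
        if len(idx) <= n_per_sex:
            if len(idx) < n_per_sex:
                warnings.warn(
                    f"stratum {stratum!r} has only {len(idx)} rows "
                    f"(< n_per_sex={n_per_sex}); using all of them")
            take[idx] = True
        else:
            take[rng.choice(idx, size=n_per_sex, replace=False)] = True
    sex = matrix.sex[take]
    return ComorbidityMatrix(matrix.data[take], sex)


# ---------------------------------------------------------------------------
# full ETL pass


def run_etl(
    records: pd.DataFrame,
    rules: Sequence[RecodeRule],
    allowlist: Iterable[str] | None = None,
    *,
    min_prevalence: float = 0.01,
    age_range: tuple[int, int] = (60, 99),
    n_top: int = 5,
    n_comorbid: int = 40,
    prevalence_denominator: str = "patients",
    panel_names: Mapping[str, str] | None = None,
) -> tuple[ComorbidityMatrix, DiseasePanel, ExclusionReport]:
    """Raw records -> (binary matrix, disease panel, exclusion report).

    Stage order: age window, visit deduplication, recoding (with re-merge),
    then the four-stage exclusion cascade, then panel construction and the
    matrix pivot.  ``allowlist`` defaults to the recode-rule target labels.
    """
    report = ExclusionReport()
    if allowlist is None:
        allowlist = [r.new_code for r in rules]
    step = filter_age(records, age_range, report)
    step = deduplicate(step, report)
    step = apply_recoding(step, rules, report)
    step, report = apply_exclusions(
        step, allowlist, min_prevalence,
        prevalence_denominator=prevalence_denominator, report=report)
    panel = build_panel(step, n_top=n_top, n_comorbid=n_comorbid, names=panel_names)
    matrix = build_matrix(step, panel)
    return matrix, panel, report
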