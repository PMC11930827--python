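"""Synthetic data with known ground truth.

Two generators back the validation story for a pipeline whose real input (a
municipal claims registry) cannot be redistributed:

* planted Ising networks plus a systematic-scan Gibbs sampler, used to test
  the network estimator and the community detector against a known graph;
* messy raw visit-record files with a :class:`RecordLedger` that records every
  injected artefact (duplicate visits, garbled codes, non-chronic diagnoses,
  out-of-window ages, single-disease patients, mergeable code pairs, a
  deliberately rare disease), so the ETL exclusion cascade can be checked
  count-for-count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import gibbs_chain
from .etl import ComorbidityMatrix, DiseasePanel, RecodeRule, default_panel

__all__ = [
    "GroundTruth",
    "RecordLedger",
    "make_planted_network",
    "gibbs_sample",
    "exact_configuration_probs",
    "make_record_file",
]


@dataclass
class GroundTruth:
    """A known pairwise binary Markov random field (Ising model).

    ``weights`` is symmetric with zero diagonal; ``thresholds`` holds the
    per-node baseline propensities; ``partition`` optionally records the
    planted community of each node.
    """

    weights: np.ndarray
    thresholds: np.ndarray
    labels: list[str]
    partition: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("ground-truth weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("ground-truth weight matrix must have zero diagonal")
        self.weights = w
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.partition is not None:
            self.partition = np.asarray(self.partition)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        """Upper-triangle (i, j) pairs with a non-zero weight."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return set(zip(i.tolist(), j.tolist()))

    def to_tsv(self, edge_path: str | Path, threshold_path: str | Path) -> None:
        rows = [(self.labels[i], self.labels[j], self.weights[i, j])
                for i, j in sorted(self.edge_set())]
        pd.DataFrame(rows, columns=["i", "j", "weight"]).to_csv(
            edge_path, sep="\t", index=False)
        pd.DataFrame({"node": self.labels, "threshold": self.thresholds}).to_csv(
            threshold_path, sep="\t", index=False)


def make_planted_network(
    p: int,
    k: int,
    w_in: float,
    w_out: float = 0.0,
    b: float = -1.0,
    *,
    density: float = 1.0,
    seed: int = 0,
    labels: list[str] | None = None,
) -> GroundTruth:
    """Plant ``k`` near-equal communities on ``p`` nodes.

    Within-block node pairs receive weight ``w_in`` independently with
    probability ``density`` (1.0 makes every block a clique, so the planted
    structure is unambiguous); between-block pairs receive ``w_out``.  All
    thresholds are ``b``.
    """
    if not (p >= k >= 1):
        raise ValueError("need p >= k >= 1")
    if w_in <= 0:
        raise ValueError("w_in must be positive")
    rng = np.random.default_rng(seed)
    sizes = [p // k + (1 if r < p % k else 0) for r in range(k)]
    part = np.repeat(np.arange(k), sizes)
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if part[i] == part[j]:
                if density >= 1.0 or rng.random() < density:
                    w[i, j] = w[j, i] = w_in
            elif w_out != 0.0:
                w[i, j] = w[j, i] = w_out
    if labels is None:
        labels = [f"D{i:02d}" for i in range(p)]
    return GroundTruth(w, np.full(p, float(b)), labels, part)


def gibbs_sample(
    gt: GroundTruth,
    n: int,
    *,
    burn_in: int = 500,
    thinning: int = 10,
    seed: int = 0,
    sex: str | None = None,
    as_array: bool = False,
) -> ComorbidityMatrix | np.ndarray:
    """Draw ``n`` binary rows from the Ising model by Gibbs sampling.

    A single systematic-scan chain (fixed node order) is run for ``burn_in``
    sweeps and then subsampled every ``thinning`` sweeps; each retained sweep
    becomes one row.  Reproducible for a fixed seed.
    """
    if burn_in < 0 or thinning < 1:
        raise ValueError("need burn_in >= 0 and thinning >= 1")
    arr = gibbs_chain(gt.weights, gt.thresholds, n, burn_in, thinning,
                      seed % (2**32))
    if as_array:
        return arr
    index = pd.Index([f"S{i:06d}" for i in range(n)], name="patient_id")
    data = pd.DataFrame(arr, index=index, columns=gt.labels)
    sex_series = None
    if sex is not None:
        sex_series = pd.Series(sex, index=index, name="sex")
    return ComorbidityMatrix(data, sex_series)


def exact_configuration_probs(gt: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution over all 2^p configurations (p <= ~16).

    Enumerates unnormalized probabilities exp(Σ_{i<j} w_ij x_i x_j + Σ b_i x_i)
    and normalizes.  Returns (configs, probs) with configs of shape (2^p, p).
    """
    p = gt.p
    if p > 16:
        raise ValueError("exact enumeration limited to p <= 16")
    configs = np.array(list(itertools.product((0, 1), repeat=p)), dtype=float)
    energy = (configs @ gt.thresholds
              + 0.5 * np.einsum("ci,ij,cj->c", configs, gt.weights, configs))
    energy -= energy.max()
    unnorm = np.exp(energy)
    return configs.astype(np.int8), unnorm / unnorm.sum()


# ---------------------------------------------------------------------------
# messy raw-record generation

#: age-band mix of the emulated elderly claims population (printed cohort
#: aggregates of the study population; bands partition 60-99 years)
DEFAULT_AGE_BANDS: tuple[tuple[int, int, float], ...] = (
    (60, 69, 0.4728),
    (70, 79, 0.3399),
    (80, 89, 0.1437),
    (90, 99, 0.0436),
)


@dataclass
class CohortSpec:
    """Clean-cohort parameters for :func:`make_record_file`.

    Every base patient carries at least two panel diseases (a redraw enforces
    multimorbidity), so exclusion-stage arithmetic stays predictable.  Disease
    indicators are iid Bernoulli with per-disease ``prevalence``; passing an
    ``ising`` ground truth instead draws correlated indicators by Gibbs
    sampling (rows with fewer than two diseases are rejected).
    """

    n_patients: int = 2000
    female_frac: float = 0.5
    age_bands: tuple[tuple[int, int, float], ...] = DEFAULT_AGE_BANDS
    prevalence: dict[str, float] | None = None
    ising: GroundTruth | None = None


@dataclass
class MessSpec:
    """Counts of artefacts injected into the emitted raw file."""

    n_duplicates: int = 0        # exact repeat-visit copies of base records
    n_invalid: int = 0           # records with garbled, non-ICD codes
    n_nonchronic: int = 0        # valid ICD-10 codes outside the allowlist
    n_single_patients: int = 0   # extra patients with exactly one disease
    n_out_of_age: int = 0        # extra patients outside the 60-99 window (2 records each)
    n_merge_pairs: int = 0       # patients given both raw variants of one merged label
    rare_carriers: int = 0       # carriers of a designated below-threshold disease


@dataclass
class RecordLedger:
    """What the generator actually emitted, kept for exact ETL validation."""

    panel_codes: list[str]
    n_base_patients: int
    base_assignment: np.ndarray                 # (n_base, p) binary, panel order
    n_duplicates: int = 0
    n_invalid: int = 0
    n_nonchronic: int = 0
    n_single_patients: int = 0
    n_out_of_age_records: int = 0
    n_merge_pairs: int = 0
    rare_code: str | None = None
    rare_carriers: int = 0
    rare_carrier_idx: np.ndarray | None = None
    n_records_emitted: int = 0
    sex_counts: dict[str, int] = field(default_factory=dict)
    age_band_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def disease_patient_counts(self) -> dict[str, int]:
        counts = dict(zip(self.panel_codes,
                          self.base_assignment.sum(axis=0).astype(int)))
        if self.rare_code is not None:
            counts[self.rare_code] = self.rare_carriers
        return counts

    def expected_stage_drops(self, min_prevalence: float) -> dict[str, int]:
        """Record counts each ETL stage should drop, derived from bookkeeping.

        The prevalence stage sees base patients plus injected single-disease
        patients; diseases (including the designated rare one) below the
        threshold are removed, and any patient thereby left with one disease
        falls at the single-disease stage together with the injected singles.
        """
        n_at_stage = self.n_base_patients + self.n_single_patients
        carriers = self.base_assignment.sum(axis=0).astype(int)
        # the most prevalent disease also carries the injected singles
        top = int(np.argmax(carriers)) if carriers.size else 0
        carrier_counts = carriers.copy()
        if self.n_single_patients:
            carrier_counts[top] += self.n_single_patients
        below = carrier_counts / max(n_at_stage, 1) < min_prevalence
        rare_dropped = (self.rare_code is not None and self.rare_carriers > 0
                        and self.rare_carriers / n_at_stage < min_prevalence)
        rare_records = self.rare_carriers if rare_dropped else 0
        prevalence_drop = int(self.base_assignment[:, below].sum()) + rare_records
        single_records = self.n_single_patients if not below[top] else 0
        surviving_counts = self.base_assignment[:, ~below].sum(axis=1)
        if (self.rare_code is not None and self.rare_carriers > 0
                and not rare_dropped and self.rare_carrier_idx is not None):
            surviving_counts = surviving_counts.copy()
            surviving_counts[self.rare_carrier_idx] += 1
        single_records += int((surviving_counts == 1).sum())
        return {
            "age-window": self.n_out_of_age_records,
            "deduplicate": self.n_duplicates,
            "recode-merge": self.n_merge_pairs,
            "invalid-code": self.n_invalid,
            "non-chronic": self.n_nonchronic,
            "low-prevalence": prevalence_drop,
            "single-disease": single_records,
        }


def _raw_variants(rule: RecodeRule) -> list[str]:
    """Concrete raw ICD-10 codes matching each source of a rule."""
    out = []
    for src in rule.sources:
        out.append(src if "." in src else src + ".0")
    return out


def _default_prevalence(codes: list[str]) -> dict[str, float]:
    """Smoothly declining prevalences, 45% down to 3%, mimicking a chronic
    disease panel ordered by frequency."""
    p = len(codes)
    vals = 0.45 * np.exp(-2.7 * np.arange(p) / max(p - 1, 1)) + 0.02
    return dict(zip(codes, vals))


def make_record_file(
    cohort: CohortSpec | None = None,
    mess: MessSpec | None = None,
    seed: int = 0,
    *,
    panel: DiseasePanel | None = None,
    rules: list[RecodeRule] | None = None,
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, RecordLedger]:
    """Emit a raw visit-record table with known, fully-ledgered mess.

    Base patients carry >= 2 panel diseases (raw, pre-recoding codes); the
    artefacts of ``mess`` are then injected on top and counted.  When
    ``mess.rare_carriers`` is set, the last panel disease is reserved as the
    designated rare disease: excluded from base assignment and given to
    exactly that many multimorbid patients.  If ``path`` is given the table
    is also written as CSV (gzip if the suffix says so).
    """
    cohort = cohort or CohortSpec()
    mess = mess or MessSpec()
    if panel is None or rules is None:
        panel, rules = default_panel()
    rng = np.random.default_rng(seed)

    codes = panel.codes
    rule_by_code = {r.new_code: r for r in rules}
    raw_code = {c: _raw_variants(rule_by_code[c])[0] for c in codes}

    rare_code = codes[-1] if mess.rare_carriers else None
    assignable = [c for c in codes if c != rare_code]
    prev = cohort.prevalence or _default_prevalence(codes)

    n = cohort.n_patients
    p = len(assignable)
    if cohort.ising is not None:
        if cohort.ising.p != p:
            raise ValueError("ising ground truth must have one node per assignable disease")
        rows = []
        while len(rows) < n:
            chunk = gibbs_sample(cohort.ising, 2 * n,
                                 seed=int(rng.integers(2**31)), as_array=True)
            rows.extend(r for r in chunk if r.sum() >= 2)
        assign = np.array(rows[:n], dtype=np.int8)
    else:
        probs = np.array([prev[c] for c in assignable])
        assign = (rng.random((n, p)) < probs).astype(np.int8)
        short = assign.sum(axis=1) < 2
        while short.any():
            assign[short] = (rng.random((short.sum(), p)) < probs).astype(np.int8)
            short = assign.sum(axis=1) < 2

    # demographics
    sexes = np.where(rng.random(n) < cohort.female_frac, "female", "male")
    band_probs = np.array([w for _, _, w in cohort.age_bands], dtype=float)
    band_probs = band_probs / band_probs.sum()
    band_idx = rng.choice(len(cohort.age_bands), size=n, p=band_probs)
    ages = np.array([rng.integers(cohort.age_bands[b][0], cohort.age_bands[b][1] + 1)
                     for b in band_idx])

    pids = [f"P{i:06d}" for i in range(n)]
    recs: list[tuple[str, str, int, str]] = []
    for i in range(n):
        for j in np.flatnonzero(assign[i]):
            recs.append((pids[i], sexes[i], int(ages[i]), raw_code[assignable[j]]))

    ledger = RecordLedger(
        panel_codes=assignable,
        n_base_patients=n,
        base_assignment=assign,
        rare_code=rare_code,
    )

    # rare-disease carriers: multimorbid base patients, one extra record each
    if mess.rare_carriers:
        carriers = rng.choice(n, size=mess.rare_carriers, replace=False)
        for i in carriers:
            recs.append((pids[i], sexes[i], int(ages[i]), raw_code[rare_code]))
        ledger.rare_carriers = mess.rare_carriers
        ledger.rare_carrier_idx = np.sort(carriers)

    # mergeable raw pairs: add the second raw variant of a multi-source label
    if mess.n_merge_pairs:
        merged = next(c for c in assignable
                      if len(_raw_variants(rule_by_code[c])) >= 2)
        variant2 = _raw_variants(rule_by_code[merged])[1]
        col = assignable.index(merged)
        carriers = np.flatnonzero(assign[:, col])
        if len(carriers) < mess.n_merge_pairs:
            raise ValueError("not enough carriers for requested merge pairs")
        for i in rng.choice(carriers, size=mess.n_merge_pairs, replace=False):
            recs.append((pids[i], sexes[i], int(ages[i]), variant2))
        ledger.n_merge_pairs = mess.n_merge_pairs

    # exact repeat visits
    if mess.n_duplicates:
        for ri in rng.choice(len(recs), size=mess.n_duplicates, replace=False):
            recs.append(recs[ri])
        ledger.n_duplicates = mess.n_duplicates

    # garbled codes (attached to existing patients; never valid, never recodable)
    for k in range(mess.n_invalid):
        i = int(rng.integers(n))
        recs.append((pids[i], sexes[i], int(ages[i]), f"bad#{k:04d}"))
    ledger.n_invalid = mess.n_invalid

    # valid but non-chronic diagnoses (letters no panel source uses)
    nonchronic_pool = [f"{letter}{num:02d}.{sub}"
                       for letter in "ABCZ" for num in range(100) for sub in range(10)]
    picks = rng.choice(len(nonchronic_pool), size=mess.n_nonchronic, replace=False)
    for k in range(mess.n_nonchronic):
        i = int(rng.integers(n))
        recs.append((pids[i], sexes[i], int(ages[i]), nonchronic_pool[picks[k]]))
    ledger.n_nonchronic = mess.n_nonchronic

    # single-disease patients: one record of the most prevalent disease
    top_code = assignable[int(np.argmax(assign.sum(axis=0)))]
    for k in range(mess.n_single_patients):
        age = int(rng.integers(60, 100))
        sex = "female" if rng.random() < 0.5 else "male"
        recs.append((f"S{k:05d}", sex, age, raw_code[top_code]))
    ledger.n_single_patients = mess.n_single_patients

    # out-of-window patients: two diseases each, age outside [60, 99]
    for k in range(mess.n_out_of_age):
        age = int(rng.integers(30, 60)) if rng.random() < 0.5 else int(rng.integers(100, 110))
        sex = "female" if rng.random() < 0.5 else "male"
        pid = f"Y{k:05d}"
        recs.append((pid, sex, age, raw_code[assignable[0]]))
        recs.append((pid, sex, age, raw_code[assignable[1]]))
    ledger.n_out_of_age_records = 2 * mess.n_out_of_age

    frame = pd.DataFrame(recs, columns=["patient_id", "sex", "age", "icd10"])
    frame = frame.sample(frac=1.0, random_state=int(rng.integers(2**31))
                         ).reset_index(drop=True)
    ledger.n_records_emitted = len(frame)
    base = frame[frame["patient_id"].str.startswith("P")]
    ledger.sex_counts = base.groupby("sex")["patient_id"].nunique().to_dict()
    for lo, hi, _ in cohort.age_bands:
        band = base[(base["age"] >= lo) & (base["age"] <= hi)]
        ledger.age_band_counts[(lo, hi)] = int(band["patient_id"].nunique())

    if path is not None:
        frame.to_csv(path, index=False)
    return frame, ledger
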