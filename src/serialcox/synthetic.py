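"""Synthetic report corpora with known hazard structure.

The generator emulates a rectal-cancer MRI report cohort: each patient
has 1-4 serial dated reports (most patients have a single report), the
report text mixes neutral radiology boilerplate with prognostic phrases
("t3", "crm threatening", "mesorectal fat infiltration", ...), and the
presence of a prognostic phrase multiplies the patient's hazard.  Latent
survival is exponential under proportional hazards,

    T ~ Exponential(rate = lambda0 * exp(eta)),   eta = sum_k beta_k x_k,

right-censored by an administrative horizon with staggered study entry
(follow-up cap uniform on (0, horizon)) and, optionally, an independent
exponential censoring time.

A "response" mechanism makes serial reports informative: a responding
patient's later reports drop their highest-hazard phrase and the hazard
is computed from the phrases in the *last* report (current disease
status), so the first report alone overstates that patient's risk.  A
symmetric "progression" mechanism can add a phrase instead.  Everything
is reproducible from the config seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .corpus import Cohort, PatientRecord, Report, SurvivalOutcome

__all__ = [
    "RiskTerm",
    "SynthConfig",
    "sample_survival",
    "generate_cohort",
    "default_risk_terms",
    "default_filler_vocab",
]

_STUDY_START = _dt.date(2012, 4, 1)
_DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class RiskTerm:
    """A prognostic phrase: its log-hazard contribution and prevalence."""

    phrase: str
    log_hazard: float
    prevalence: float

    def __post_init__(self) -> None:
        if not self.phrase.strip():
            raise ValueError("risk-term phrase must be non-empty")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")


def default_risk_terms() -> list[RiskTerm]:
    """Prognostic phrases emulating rectal-MRI findings, with hazards."""
    return [
        RiskTerm("crm threatening", 1.2, 0.15),
        RiskTerm("mesorectal fat infiltration", 0.9, 0.25),
        RiskTerm("t3", 0.7, 0.35),
        RiskTerm("enlarged lymph node", 0.8, 0.20),
        RiskTerm("suspicious regional lymph node metastases", 1.0, 0.10),
        RiskTerm("no significant lymph node enlargements", -0.8, 0.30),
    ]


def default_filler_vocab() -> list[str]:
    """Neutral radiology boilerplate; punctuation/hyphens stress the tokenizer."""
    return [
        "rectal MRI with contrast.",
        "axial and sagittal T2-weighted images were obtained,",
        "no interval change since prior study.",
        "the visualized bladder is unremarkable;",
        "post-contrast enhancement pattern is preserved.",
        "mild wall thickening of the distal rectum,",
        "the sigmoid colon appears normal.",
        "no free fluid in the pelvis.",
        "impression:",
        "findings:",
        "correlate clinically.",
        "bone marrow signal within normal limits.",
        "small field-of-view high-resolution sequences,",
        "sphincter complex is intact.",
        "levator ani muscles are symmetric.",
        "no pelvic side-wall abnormality.",
        "prostate and seminal vesicles unremarkable.",
        "the uterus and adnexa are within normal limits.",
        "comparison: prior rectal MRI.",
        "diffusion-weighted imaging was performed,",
        "anal verge distance measured on sagittal images.",
        "presacral space is preserved.",
        "no bone lesion identified.",
        "degenerative changes of the lumbosacral spine,",
        "incidental Tarlov cyst.",
        "motion artifact mildly limits evaluation.",
        "bowel preparation adequate.",
        "stranding of perirectal fat is minimal,",
        "surgical clips from prior procedure.",
        "recommend follow-up imaging.",
    ]


@dataclass
class SynthConfig:
    """Full description of a synthetic cohort; same config => same corpus."""

    n_patients: int = 1000
    risk_terms: list[RiskTerm] = field(default_factory=default_risk_terms)
    filler_vocab: list[str] = field(default_factory=default_filler_vocab)
    baseline_rate: float = 0.0016  # events per month (lambda0)
    admin_censor_horizon: float = 90.0  # months
    censor_rate: float = 0.0  # optional independent exponential censoring
    staggered_entry: bool = True  # follow-up cap ~ U(0, horizon)
    report_count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.58, 2: 0.33, 3: 0.06, 4: 0.03}
    )
    tokens_per_report: tuple[int, int] = (15, 40)
    response_prob: float = 0.0  # later reports drop the worst phrase
    progression_prob: float = 0.0  # later reports gain a phrase
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate (lambda0) must be > 0")
        if abs(sum(self.report_count_probs.values()) - 1.0) > 1e-9:
            raise ValueError("report_count_probs must sum to 1")
        if any(k < 1 for k in self.report_count_probs):
            raise ValueError("report counts must be >= 1")
        lo, hi = self.tokens_per_report
        if lo < 1 or hi < lo:
            raise ValueError(f"bad tokens_per_report range {self.tokens_per_report}")
        if not self.filler_vocab and hi > 0:
            raise ValueError("filler_vocab is empty but reports need filler tokens")
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must be in [0,1]")
        if not 0.0 <= self.progression_prob <= 1.0:
            raise ValueError("progression_prob must be in [0,1]")


def sample_survival(
    linear_predictor: float,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> SurvivalOutcome:
    """Draw one right-censored outcome under the proportional-hazards process.

    Latent T ~ Exp(lambda0 * exp(eta)); the follow-up cap is the
    administrative horizon (scaled by a uniform draw under staggered
    entry) and, if ``censor_rate`` > 0, an independent exponential
    censoring time competes as well.  event = 1 iff T is the minimum.
    """
    if not np.isfinite(linear_predictor):
        raise ValueError("linear predictor must be finite")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rate = config.baseline_rate * np.exp(linear_predictor)
    latent = rng.exponential(1.0 / rate) if np.isfinite(rate) else 0.0
    cap = config.admin_censor_horizon
    if config.staggered_entry and np.isfinite(cap):
        cap = cap * rng.uniform()
    elif config.staggered_entry:
        rng.uniform()  # keep the draw sequence stable across horizons
    censor = rng.exponential(1.0 / config.censor_rate) if config.censor_rate > 0 else np.inf
    observed = min(latent, cap, censor)
    return SurvivalOutcome(time=float(observed), event=int(latent <= min(cap, censor)))


def _compose_report_text(
    rng: np.random.Generator,
    filler: list[str],
    phrases: list[str],
    n_tokens: int,
) -> str:
    """Shuffled boilerplate up to ~n_tokens, with risk phrases spliced in."""
    chunks: list[str] = []
    count = 0
    while count < n_tokens:
        piece = filler[int(rng.integers(len(filler)))]
        chunks.append(piece)
        count += len(piece.split())
    for phrase in phrases:
        pos = int(rng.integers(len(chunks) + 1))
        chunks.insert(pos, phrase)
    return " ".join(chunks)


def generate_cohort(config: SynthConfig, name: str = "synthetic") -> Cohort:
    """Generate a synthetic cohort; byte-identical for identical config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = sorted(config.report_count_probs)
    probs = np.array([config.report_count_probs[k] for k in counts], dtype=float)
    lo, hi = config.tokens_per_report
    pos_terms = [t for t in config.risk_terms if t.log_hazard > 0]

    records = []
    width = max(4, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        k = int(rng.choice(counts, p=probs))
        present = [t for t in config.risk_terms if rng.uniform() < t.prevalence]

        # per-report phrase sets; hazard follows the *last* report's phrases
        per_report = [list(present) for _ in range(k)]
        if k >= 2 and per_report[0]:
            u = rng.uniform()
            present_pos = [t for t in present if t.log_hazard > 0]
            if u < config.response_prob and present_pos:
                worst = max(present_pos, key=lambda t: t.log_hazard)
                for later in per_report[1:]:
                    later.remove(worst)
            elif u < config.response_prob + config.progression_prob:
                absent = [t for t in pos_terms if t not in present]
                if absent:
                    gained = absent[int(rng.integers(len(absent)))]
                    for later in per_report[1:]:
                        later.append(gained)

        eta = float(sum(t.log_hazard for t in per_report[-1]))
        outcome = sample_survival(eta, config, rng)

        entry_months = rng.uniform(0.0, config.admin_censor_horizon) \
            if np.isfinite(config.admin_censor_horizon) else 0.0
        date = _STUDY_START + _dt.timedelta(days=entry_months * _DAYS_PER_MONTH)
        reports = []
        for j in range(k):
            n_tokens = int(rng.integers(lo, hi + 1))
            phrases = [t.phrase for t in per_report[j]]
            text = _compose_report_text(rng, config.filler_vocab, phrases, n_tokens)
            reports.append(Report(patient_id=pid, date=date, text=text))
            date = date + _dt.timedelta(days=float(rng.uniform(2.0, 6.0)) * _DAYS_PER_MONTH)
        records.append(PatientRecord(pid, tuple(reports), outcome))
    return Cohort(tuple(records), name=name)
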