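"""Synthetic pregnancy-cohort and test-strip image simulator.

Emulates the data-generating process the analysis pipeline assumes: a
cohort of pregnant women enrolled around gestational week 20 who perform a
weekly salivary colorimetric self-test until delivery. Each test strip
turns from white toward purple as salivary uric acid (sUA) rises; the
simulator drives strip color with a latent per-participant sUA signal and
renders small RGB strip ROIs.

Model
-----
* Outcomes. Pre-eclampsia (PE) and pregnancy-induced hypertension (PIH)
  are mutually exclusive (PIH here means hypertension without progression
  to PE); the PE draw takes precedence. Intrauterine growth restriction
  (IUGR) may co-occur with either, and is more frequent inside the PE
  stratum (conditional probability ``p_iugr_given_pe``). Outside the PE
  stratum the IUGR probability is solved so that the *marginal* IUGR
  frequency converges to ``prevalence_iugr``.
* Delivery week. Drawn from a categorical distribution over gestational-age
  bands (<32, 32–34, 34–37, 37–40, >40 weeks) whose weights depend on the
  outcome: growth-restricted and hypertensive pregnancies deliver earlier.
* Latent sUA. For participant *i* at week *t*:
  ``z_it = b_i + iugr_effect·[IUGR] + pe_effect·[hypertensive, t ≥ onset−4] + e_it``
  with ``b_i ~ N(sua_baseline_mean, sua_between_sd)`` and
  ``e_it ~ N(0, sua_within_sd)`` — a wide within-person weekly fluctuation,
  a persistent darkness shift for IUGR from enrollment on (placental
  origin), and a small late shift for hypertensive outcomes.
* Compliance. Each participant has her own weekly submission probability
  drawn from a Beta distribution with mean ``compliance_rate``; weeks are
  then independent Bernoulli. The Beta spread reproduces the strongly
  overdispersed compliance seen in self-testing cohorts (rates spanning
  0–100%, with a sizeable fully-compliant fraction).
* Rendering. The strip color interpolates from white (255,255,255) toward
  a deep purple anchor along a logistic ramp in the latent signal, with a
  saturation gradient across the strip (one end darkest, so the per-test
  minimum is informative) and i.i.d. Gaussian 8-bit pixel noise.

Every participant draws from her own PRNG stream derived from the master
seed, so enlarging the cohort never perturbs earlier participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "SimulationConfig",
    "Participant",
    "Cohort",
    "generate_cohort",
    "render_strip_image",
    "write_cohort",
    "read_cohort",
    "simulate_features",
]

# Deep-purple RGB anchor of the fully developed strip color.
PURPLE_ANCHOR = np.array([80.0, 20.0, 110.0])
WHITE = np.array([255.0, 255.0, 255.0])

# Gestational-age-at-delivery bands (completed weeks) and per-outcome weights.
# Bands: <32, 32-34, 34-37, 37-40, >40. Weights reflect that IUGR and
# hypertensive pregnancies deliver earlier than uncomplicated ones.
_DELIVERY_BANDS = [(28, 31), (32, 33), (34, 36), (37, 39), (40, 42)]
_DELIVERY_WEIGHTS = {
    "none": np.array([3, 2, 17, 150, 249], dtype=float),
    "pe": np.array([1, 0, 1, 24, 8], dtype=float),
    "pih": np.array([0, 0, 1, 8, 8], dtype=float),
    "iugr": np.array([3, 1, 2, 4, 0], dtype=float),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults reproduce the target
    study structure (n = 495; PE 6.9%, PIH 3.4%, IUGR 2.0%; IUGR in 14.7%
    of PE; mean weekly compliance 67%)."""

    n_participants: int = 495
    prevalence_pe: float = 0.069
    prevalence_pih: float = 0.034
    prevalence_iugr: float = 0.020
    p_iugr_given_pe: float = 0.147
    compliance_rate: float = 0.67
    compliance_concentration: float = 1.2
    enrollment_week: int = 20
    sua_baseline_mean: float = 1.0
    sua_between_sd: float = 0.7
    sua_within_sd: float = 0.8
    iugr_effect: float = 5.0
    pe_effect: float = 0.25
    strip_rows: int = 16
    strip_cols: int = 16
    pixel_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = {
            "prevalence_pe": self.prevalence_pe,
            "prevalence_pih": self.prevalence_pih,
            "prevalence_iugr": self.prevalence_iugr,
            "p_iugr_given_pe": self.p_iugr_given_pe,
            "compliance_rate": self.compliance_rate,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("sua_between_sd", "sua_within_sd", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.strip_rows < 4 or self.strip_cols < 4:
            raise ValueError("strip dimensions must be at least 4×4")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.compliance_concentration <= 0:
            raise ValueError("compliance_concentration must be > 0")
        if self.p_iugr_outside_pe() < 0:
            raise ValueError(
                "prevalence_iugr is too small relative to "
                "prevalence_pe * p_iugr_given_pe"
            )

    def p_iugr_outside_pe(self) -> float:
        """IUGR probability outside the PE stratum, solved so the marginal
        IUGR frequency equals ``prevalence_iugr``."""
        if self.prevalence_pe >= 1.0:
            return 0.0
        return (self.prevalence_iugr - self.prevalence_pe * self.p_iugr_given_pe) / (
            1.0 - self.prevalence_pe
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class Participant:
    id: str
    enrollment_week: int
    delivery_week: int
    outcome_pe: bool = False
    outcome_pih: bool = False
    outcome_iugr: bool = False
    event_week_pe: int | None = None
    event_week_pih: int | None = None
    event_week_iugr: int | None = None

    def __post_init__(self):
        if self.outcome_pe and self.outcome_pih:
            raise ValueError("PE and PIH are mutually exclusive")
        if self.delivery_week < self.enrollment_week + 1:
            raise ValueError("delivery_week must be at least enrollment_week + 1")
        for w in (self.event_week_pe, self.event_week_pih, self.event_week_iugr):
            if w is not None and not (self.enrollment_week < w <= self.delivery_week):
                raise ValueError("event weeks must lie in (enrollment, delivery]")


@dataclass
class Cohort:
    participants: list  # list[Participant]
    testlog: pd.DataFrame  # participant_id, week, submitted, image_path
    sua: pd.DataFrame  # participant_id, week, sua (latent units)
    config: SimulationConfig

    def participants_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "id": p.id,
                    "enrollment_week": p.enrollment_week,
                    "delivery_week": p.delivery_week,
                    "pe": p.outcome_pe,
                    "pih": p.outcome_pih,
                    "iugr": p.outcome_iugr,
                    "event_week_pe": p.event_week_pe,
                    "event_week_pih": p.event_week_pih,
                    "event_week_iugr": p.event_week_iugr,
                }
            )
        cols = ["id", "enrollment_week", "delivery_week", "pe", "pih", "iugr",
                "event_week_pe", "event_week_pih", "event_week_iugr"]
        return pd.DataFrame(rows, columns=cols)


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def _image_seed(seed: int, index: int, week: int) -> np.random.SeedSequence:
    # separate spawn branch from the participant stream (offset avoids overlap)
    return np.random.SeedSequence(seed, spawn_key=(index, 1_000_000 + week))


def _draw_event_week(rng, lo: int, enrollment: int, delivery: int) -> int:
    """Uniform integer week in [max(enrollment+1, lo), delivery]; collapses
    to the delivery week when the window is empty."""
    low = max(enrollment + 1, lo)
    if low >= delivery:
        return delivery
    return int(rng.integers(low, delivery + 1))


def _draw_delivery(rng, outcome_key: str, enrollment: int) -> int:
    w = _DELIVERY_WEIGHTS[outcome_key]
    band = int(rng.choice(len(_DELIVERY_BANDS), p=w / w.sum()))
    lo, hi = _DELIVERY_BANDS[band]
    week = int(rng.integers(lo, hi + 1))
    return max(week, enrollment + 1)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate participants, weekly test log and latent sUA trajectories.

    Deterministic given ``config.seed``; each participant consumes an
    independent PRNG stream keyed by her index.
    """
    config.validate()
    p_iugr_out = config.p_iugr_outside_pe()
    participants = []
    log_rows = []
    sua_rows = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        pid = f"P{i:05d}"

        u_pe, u_pih, u_iugr = rng.random(3)
        pe = u_pe < config.prevalence_pe
        pih = (not pe) and (u_pih < config.prevalence_pih)
        iugr = u_iugr < (config.p_iugr_given_pe if pe else p_iugr_out)

        outcome_key = "iugr" if iugr else ("pe" if pe else ("pih" if pih else "none"))
        delivery = _draw_delivery(rng, outcome_key, config.enrollment_week)

        ev_pe = ev_pih = ev_iugr = None
        if pe:
            ev_pe = _draw_event_week(rng, 33, config.enrollment_week, delivery)
        if pih:
            ev_pih = _draw_event_week(rng, 33, config.enrollment_week, delivery)
        if iugr:
            ev_iugr = _draw_event_week(rng, 28, config.enrollment_week, delivery)

        part = Participant(
            id=pid,
            enrollment_week=config.enrollment_week,
            delivery_week=delivery,
            outcome_pe=bool(pe),
            outcome_pih=bool(pih),
            outcome_iugr=bool(iugr),
            event_week_pe=ev_pe,
            event_week_pih=ev_pih,
            event_week_iugr=ev_iugr,
        )
        participants.append(part)

        weeks = np.arange(config.enrollment_week, delivery + 1)
        baseline = rng.normal(config.sua_baseline_mean, config.sua_between_sd)
        z = baseline + rng.normal(0.0, config.sua_within_sd, size=weeks.size)
        if iugr:
            z += config.iugr_effect
        if pe or pih:
            onset = (ev_pe if pe else ev_pih) - 4
            z += np.where(weeks >= onset, config.pe_effect, 0.0)

        if config.compliance_rate >= 1.0:
            p_submit = 1.0
        elif config.compliance_rate <= 0.0:
            p_submit = 0.0
        else:
            c = config.compliance_concentration
            p_submit = rng.beta(c * config.compliance_rate, c * (1.0 - config.compliance_rate))
        submitted = rng.random(weeks.size) < p_submit

        for w, zz, sub in zip(weeks, z, submitted):
            log_rows.append(
                {
                    "participant_id": pid,
                    "week": int(w),
                    "submitted": bool(sub),
                    "image_path": f"{pid}_w{int(w)}.png" if sub else None,
                }
            )
            sua_rows.append({"participant_id": pid, "week": int(w), "sua": float(zz)})

    log_cols = ["participant_id", "week", "submitted", "image_path"]
    sua_cols = ["participant_id", "week", "sua"]
    testlog = pd.DataFrame(log_rows, columns=log_cols)
    sua = pd.DataFrame(sua_rows, columns=sua_cols)
    return Cohort(participants=participants, testlog=testlog, sua=sua, config=config)


def strip_ramp(sua_level, config: SimulationConfig) -> np.ndarray:
    """Noise-free strip: white→purple logistic ramp with a column-wise
    saturation gradient (last column darkest). Returns float (H, W, 3)."""
    level = 1.0 / (1.0 + np.exp(-np.asarray(sua_level, dtype=float)))
    cols = np.linspace(0.6, 1.0, config.strip_cols)
    frac = level * cols[None, :]  # (W,) broadcast over rows
    frac = np.broadcast_to(frac, (config.strip_rows, config.strip_cols))
    return WHITE - frac[..., None] * (WHITE - PURPLE_ANCHOR)


def render_strip_image(sua_level: float, config: SimulationConfig, seed) -> np.ndarray:
    """Render one strip ROI as an (H, W, 3) uint8 array.

    The mean intensity of the underlying ramp decreases strictly with
    ``sua_level``; Gaussian pixel noise (sd ``pixel_noise_sd``) is added
    per channel, then clipped to [0, 255] and rounded to 8 bits.
    Deterministic given identical arguments and seed.
    """
    if not np.isfinite(sua_level):
        raise ValueError("sua_level must be finite")
    base = strip_ramp(sua_level, config)
    rng = np.random.Generator(np.random.PCG64(seed))
    noisy = base + rng.normal(0.0, config.pixel_noise_sd, size=base.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def _iter_submitted(cohort: Cohort):
    sua_lookup = {
        (r.participant_id, r.week): r.sua for r in cohort.sua.itertuples(index=False)
    }
    for rec in cohort.testlog.itertuples(index=False):
        if rec.submitted:
            yield rec, sua_lookup[(rec.participant_id, rec.week)]


def render_cohort_images(cohort: Cohort) -> dict[str, np.ndarray]:
    """Render every submitted test; keys are the test-log image names."""
    cfg = cohort.config
    index = {p.id: i for i, p in enumerate(cohort.participants)}
    out = {}
    for rec, sua in _iter_submitted(cohort):
        seed = _image_seed(cfg.seed, index[rec.participant_id], rec.week)
        out[rec.image_path] = render_strip_image(sua, cfg, seed)
    return out


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Serialize a cohort: participants.csv, testlog.csv, sua.csv,
    config.yaml and one PNG per submitted test under images/."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    cohort.participants_frame().to_csv(outdir / "participants.csv", index=False)
    cohort.testlog.to_csv(outdir / "testlog.csv", index=False)
    cohort.sua.to_csv(outdir / "sua.csv", index=False)
    cohort.config.to_yaml(outdir / "config.yaml")
    for name, img in render_cohort_images(cohort).items():
        Image.fromarray(img, mode="RGB").save(outdir / "images" / name)
    return outdir


def read_cohort(outdir) -> Cohort:
    """Load a serialized cohort (images stay on disk)."""
    outdir = Path(outdir)
    config = SimulationConfig.from_yaml(outdir / "config.yaml")
    pdf = pd.read_csv(outdir / "participants.csv")
    participants = []
    for r in pdf.itertuples(index=False):
        def _ev(v):
            return None if pd.isna(v) else int(v)
        participants.append(
            Participant(
                id=str(r.id),
                enrollment_week=int(r.enrollment_week),
                delivery_week=int(r.delivery_week),
                outcome_pe=bool(r.pe),
                outcome_pih=bool(r.pih),
                outcome_iugr=bool(r.iugr),
                event_week_pe=_ev(r.event_week_pe),
                event_week_pih=_ev(r.event_week_pih),
                event_week_iugr=_ev(r.event_week_iugr),
            )
        )
    testlog = pd.read_csv(outdir / "testlog.csv")
    testlog["image_path"] = testlog["image_path"].where(testlog["submitted"], None)
    sua = pd.read_csv(outdir / "sua.csv")
    return Cohort(participants=participants, testlog=testlog, sua=sua, config=config)


def simulate_features(config: SimulationConfig):
    """Simulate a cohort and extract its feature table fully in memory.

    Returns ``(participants_frame, testlog, features)`` where ``features``
    is the standard extraction output (72 schema variables plus
    combined_rgb_min, one row per submitted test). Equivalent to
    write_cohort → extract_cohort_features without touching disk.
    """
    from .colorimetry import extract_features_batch

    cohort = generate_cohort(config)
    cfg = cohort.config
    index = {p.id: i for i, p in enumerate(cohort.participants)}
    imgs, pids, weeks = [], [], []
    for rec, sua in _iter_submitted(cohort):
        seed = _image_seed(cfg.seed, index[rec.participant_id], rec.week)
        imgs.append(render_strip_image(sua, cfg, seed))
        pids.append(rec.participant_id)
        weeks.append(int(rec.week))
    if imgs:
        features = extract_features_batch(np.stack(imgs), pids, weeks)
    else:
        from .colorimetry import COMBINED_RGB_COLUMN, FEATURE_SCHEMA

        features = pd.DataFrame(
            columns=["participant_id", "week", *FEATURE_SCHEMA, COMBINED_RGB_COLUMN]
        )
    return cohort.participants_frame(), cohort.testlog, features
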