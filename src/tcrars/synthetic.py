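"""Synthetic TCRβ cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
case repertoires enriched for tail-localized signal motifs (contiguous and
gapped) with biased J usage on motif-carrying clones, Zipf-like clone
frequency spectra, and clinical covariates coupled to each case's signal
burden through a latent linear-Gaussian activity variable.  Every draw is
driven by one seed, and the ground truth (planted motifs, per-subject
burden, covariate parameters) is emitted alongside the cohort so recovery
tests are self-documenting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParameterError
from .repertoire_io import (
    ClinicalRecord,
    Clonotype,
    Cohort,
    Repertoire,
    write_repertoire,
)
from .saliency import PATTERNS

#: Interior residue composition for background junctions, approximating the
#: glycine/serine-rich usage of human CDR3β loops.  All 20 residues occur;
#: cysteine is rare and phenylalanine modest, as in real junction interiors
#: (the terminal C/F anchors are written explicitly).
INTERIOR_COMPOSITION: dict[str, float] = {
    "A": 0.055, "C": 0.015, "D": 0.045, "E": 0.055, "F": 0.040,
    "G": 0.125, "H": 0.020, "I": 0.030, "K": 0.025, "L": 0.080,
    "M": 0.012, "N": 0.040, "P": 0.045, "Q": 0.055, "R": 0.055,
    "S": 0.130, "T": 0.070, "V": 0.045, "W": 0.013, "Y": 0.045,
}

_INTERIOR_LETTERS = np.array(list(INTERIOR_COMPOSITION))
_INTERIOR_WEIGHTS = np.array(list(INTERIOR_COMPOSITION.values()))
_INTERIOR_WEIGHTS = _INTERIOR_WEIGHTS / _INTERIOR_WEIGHTS.sum()

TRBV_PANEL = (
    "TRBV2*01", "TRBV4-1*01", "TRBV5-1*01", "TRBV6-2*01", "TRBV6-5*01",
    "TRBV7-9*01", "TRBV9*01", "TRBV10-3*01", "TRBV11-2*01", "TRBV12-3*01",
    "TRBV13*01", "TRBV14*01", "TRBV15*01", "TRBV18*01", "TRBV19*01",
    "TRBV20-1*01", "TRBV25-1*01", "TRBV27*01", "TRBV28*01", "TRBV29-1*01",
)

TRBJ_PANEL = (
    "TRBJ1-1*01", "TRBJ1-2*01", "TRBJ1-3*01", "TRBJ1-4*01", "TRBJ1-5*01",
    "TRBJ1-6*01", "TRBJ2-1*01", "TRBJ2-2*01", "TRBJ2-3*01", "TRBJ2-4*01",
    "TRBJ2-5*01", "TRBJ2-6*01", "TRBJ2-7*01",
)

#: Four contiguous 3-mers and two gapped mers.  The gapped pair is chosen
#: to have a low chance-collision rate with the background composition
#: (rare interior residues M, I/D), so that planted tail localization is
#: measurable rather than swamped by coincidental matches.
DEFAULT_SIGNAL_MOTIFS = ("AFF", "LFF", "IYF", "YTF", "I*DR", "SM*L")

DEFAULT_J_BIAS = {
    "AFF": "TRBJ1-1*01",
    "LFF": "TRBJ1-3*01",
    "IYF": "TRBJ2-2*01",
    "YTF": "TRBJ1-2*01",
    "I*DR": "TRBJ2-7*01",
    "SM*L": "TRBJ2-1*01",
}


def _motif_pattern(motif: str) -> str:
    if "*" not in motif:
        return "XXX"
    if len(motif) == 4 and motif[1] == "*":
        return "X*XX"
    if len(motif) == 4 and motif[2] == "*":
        return "XX*X"
    raise ParameterError(f"unsupported motif shape: {motif!r}")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults are the package's standard scenario: 60 cases / 60 controls,
    500 clonotypes per subject, four contiguous and two gapped planted
    motifs, per-case enrichment 0.15 (with relative spread so burden varies
    across cases) against background 0.01, tail planting, Zipf exponent
    1.2.
    """

    n_cases: int = 60
    n_controls: int = 60
    clonotypes_per_subject: int = 500
    length_mean: float = 14.5
    length_sd: float = 2.0
    signal_motifs: tuple[str, ...] = DEFAULT_SIGNAL_MOTIFS
    enrichment_rate: float = 0.15
    background_rate: float = 0.01
    enrichment_spread: float = 2.0 / 3.0  # relative half-width of per-case rates
    planted_region: str = "tail"
    j_bias: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_J_BIAS))
    zipf_exponent: float = 1.2
    activity_coupling: float = 3.5
    noise_sd: float = 0.1
    seed: int = 20240101

    def __post_init__(self):
        if not 0.0 <= self.background_rate <= self.enrichment_rate <= 1.0:
            raise ParameterError("need 0 <= background_rate <= enrichment_rate <= 1")
        if self.clonotypes_per_subject < 10:
            raise ParameterError("clonotypes_per_subject must be >= 10")
        if self.planted_region not in ("tail", "uniform"):
            raise ParameterError("planted_region must be 'tail' or 'uniform'")


@dataclass
class GroundTruth:
    signal_motifs: tuple[str, ...]
    burden: dict[str, float]            # subject -> planted clonotype fraction
    case_rates: dict[str, float]        # subject -> per-case planting rate
    activity: dict[str, float]          # subject -> latent activity A
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "signal_motifs": list(self.signal_motifs),
                "burden": self.burden,
                "case_rates": self.case_rates,
                "activity": self.activity,
                "params": self.params,
            },
            sort_keys=True,
            indent=1,
        )


def sample_background_cdr3(rng: np.random.Generator, length_mean: float, length_sd: float) -> str:
    """One background junction: C + interior draws + F, length in [8, 24]."""
    L = int(np.clip(round(rng.normal(length_mean, length_sd)), 8, 24))
    interior = rng.choice(_INTERIOR_LETTERS, size=L - 2, p=_INTERIOR_WEIGHTS)
    return "C" + "".join(interior) + "F"


def plant_motif(junction: str, motif: str, region: str, rng: np.random.Generator) -> tuple[str, bool]:
    """Write a motif into a junction without changing its length.

    The window start is uniform within the tail third (region='tail') or
    anywhere (region='uniform'), never overwriting the first or last
    residue.  Gapped motifs write only their X positions.  Returns the new
    junction and a flag (False when the junction was too short to plant).
    """
    pattern = _motif_pattern(motif)
    span, masked, _ = PATTERNS[pattern]
    L = len(junction)
    hi = L - 1 - span  # last start keeping the terminal residue intact
    lo = 1 if region == "uniform" else max(1, (2 * L) // 3)
    if hi < lo:  # window cannot sit in the requested region
        return junction, False
    start = int(rng.integers(lo, hi + 1))
    chars = list(junction)
    for k in masked:
        chars[start + k] = motif[k]
    return "".join(chars), True


def _zipf_frequencies(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    rng.shuffle(w)  # decouple frequency rank from generation order
    return w / w.sum()


def generate_repertoire(
    subject_id: str,
    label: str,
    rate: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Repertoire, float]:
    """One repertoire with unique junctions; returns (repertoire, burden)."""
    n = cfg.clonotypes_per_subject
    junctions: list[str] = []
    planted_motifs: list[str | None] = []
    seen: set[str] = set()
    while len(junctions) < n:
        j = sample_background_cdr3(rng, cfg.length_mean, cfg.length_sd)
        motif = None
        if rng.random() < rate:
            motif = cfg.signal_motifs[int(rng.integers(len(cfg.signal_motifs)))]
            j2, ok = plant_motif(j, motif, cfg.planted_region, rng)
            if ok:
                j = j2
            else:
                motif = None
        if j in seen:
            continue
        seen.add(j)
        junctions.append(j)
        planted_motifs.append(motif)
    freqs = _zipf_frequencies(n, cfg.zipf_exponent, rng)
    clonotypes = []
    for j, motif, f in zip(junctions, planted_motifs, freqs):
        v = TRBV_PANEL[int(rng.integers(len(TRBV_PANEL)))]
        if motif is not None and motif in cfg.j_bias:
            jcall = cfg.j_bias[motif]
        else:
            jcall = TRBJ_PANEL[int(rng.integers(len(TRBJ_PANEL)))]
        clonotypes.append(
            Clonotype(junction_aa=j, v_call=v, j_call=jcall, frequency=float(f))
        )
    burden = sum(m is not None for m in planted_motifs) / n
    return Repertoire(subject_id, label, clonotypes), float(burden)


def generate_cohort(cfg: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """A full labeled cohort plus its ground truth, reproducible by seed.

    Case clinical covariates derive from latent activity
    A = coupling * burden + N(0, noise_sd): SLEDAI = round(max(0, 10 A)),
    C3 = 120 - 40 A + noise, C4 = 30 - 10 A + noise, dsDNA positive iff A
    above the case median, damage count from activity quintiles.  Controls
    get SLEDAI 0 and healthy-baseline complement levels.
    """
    rng = np.random.default_rng(cfg.seed)
    reps: list[Repertoire] = []
    burden: dict[str, float] = {}
    case_rates: dict[str, float] = {}
    lo = 1.0 - cfg.enrichment_spread
    hi = 1.0 + cfg.enrichment_spread
    for i in range(cfg.n_cases):
        sid = f"case_{i:03d}"
        rate = float(
            np.clip(
                cfg.enrichment_rate * rng.uniform(lo, hi),
                cfg.background_rate, 1.0,
            )
        )
        rep, b = generate_repertoire(sid, "case", rate, cfg, rng)
        reps.append(rep)
        burden[sid] = b
        case_rates[sid] = rate
    for i in range(cfg.n_controls):
        sid = f"control_{i:03d}"
        rep, b = generate_repertoire(sid, "control", cfg.background_rate, cfg, rng)
        reps.append(rep)
        burden[sid] = b

    activity: dict[str, float] = {}
    case_ids = [f"case_{i:03d}" for i in range(cfg.n_cases)]
    a_vals = np.array(
        [
            cfg.activity_coupling * burden[sid] + rng.normal(0.0, cfg.noise_sd)
            for sid in case_ids
        ]
    )
    med = float(np.median(a_vals)) if len(a_vals) else 0.0
    quintiles = (
        np.quantile(a_vals, [0.2, 0.4, 0.6, 0.8]) if len(a_vals) >= 5 else None
    )
    for sid, a in zip(case_ids, a_vals):
        activity[sid] = float(a)
    for rep in reps:
        if rep.label == "case":
            a = activity[rep.subject_id]
            damage = int(np.searchsorted(quintiles, a)) if quintiles is not None else 0
            rep.clinical = ClinicalRecord(
                sledai=int(round(max(0.0, 10.0 * a))),
                c3=float(120.0 - 40.0 * a + rng.normal(0.0, 8.0)),
                c4=float(30.0 - 10.0 * a + rng.normal(0.0, 3.0)),
                dsdna_positive=bool(a > med),
                damage_count=damage,
            )
        else:
            rep.clinical = ClinicalRecord(
                sledai=0,
                c3=float(120.0 + rng.normal(0.0, 8.0)),
                c4=float(30.0 + rng.normal(0.0, 3.0)),
                dsdna_positive=False,
                damage_count=0,
            )
    truth = GroundTruth(
        signal_motifs=tuple(cfg.signal_motifs),
        burden=burden,
        case_rates=case_rates,
        activity=activity,
        params={
            "activity_coupling": cfg.activity_coupling,
            "noise_sd": cfg.noise_sd,
            "enrichment_rate": cfg.enrichment_rate,
            "background_rate": cfg.background_rate,
            "enrichment_spread": cfg.enrichment_spread,
            "zipf_exponent": cfg.zipf_exponent,
            "seed": cfg.seed,
        },
    )
    return Cohort(reps), truth


def write_cohort(cohort: Cohort, truth: GroundTruth, out_dir, dialect: str = "airr") -> None:
    """One repertoire TSV per subject + clinical.csv + ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,label,sledai,c3,c4,dsdna,damage_count"]
    for rep in cohort:
        write_repertoire(rep, out / f"{rep.subject_id}.tsv", dialect)
        c = rep.clinical or ClinicalRecord()
        rows.append(
            ",".join(
                [
                    rep.subject_id,
                    rep.label,
                    "" if c.sledai is None else str(c.sledai),
                    "" if c.c3 is None else f"{c.c3:.4f}",
                    "" if c.c4 is None else f"{c.c4:.4f}",
                    "" if c.dsdna_positive is None else str(int(c.dsdna_positive)),
                    "" if c.damage_count is None else str(c.damage_count),
                ]
            )
        )
    (out / "clinical.csv").write_text("\n".join(rows) + "\n")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")


def default_scenario(seed: int | None = None, **overrides) -> SimulationConfig:
    """The package's standard signal scenario (optionally reseeded)."""
    kwargs = dict(overrides)
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


def null_scenario(seed: int, n_subjects_per_label: int = 20, **overrides) -> SimulationConfig:
    """Type-I control: planting rate equal in cases and controls."""
    return SimulationConfig(
        n_cases=n_subjects_per_label,
        n_controls=n_subjects_per_label,
        enrichment_rate=0.01,
        background_rate=0.01,
        enrichment_spread=0.0,
        seed=seed,
        **overrides,
    )
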