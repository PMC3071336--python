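"""Synthetic impulse-oscillometry cohorts with the study's design.

Emulates a two-group paediatric cohort — Healthy (H, n=7) and small-airway
impaired (SAI, n=19) — measured at a 2006 baseline visit (pre-bronchodilator
only) and again in 2008 before and after bronchodilator. Each subject owns
latent eRIC circuit constants drawn log-normally around the group archetype
means; growth (2006→2008) and bronchodilator (pre→post, 2008) act as
per-parameter multiplicative effects; measurement adds independent Gaussian
noise to resistance and reactance at each grid frequency.

Archetype means for Rp and Cp, and the effect multipliers, follow the
group-mean trajectories reported for this design (SAI eRIC Rp
0.824→0.601→0.472 kPa·s/L, Cp 0.045→0.056→0.076 L/kPa; H Rp 0.501,
Cp 0.115 at baseline). Rc and I means are calibration choices (no published
group means exist) set so synthetic spectra resemble the published averaged
curves: R5 ≈ 0.5–0.7 kPa·s/L, Fres ≈ 15–22 Hz.

Reproducibility: one cohort seed expands into independent per-record
substreams keyed by a stable CRC-32 hash of (subject id, visit, condition),
so adding subjects never perturbs existing subjects' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .models import ERICParameters, ImpedanceSpectrum, InvalidInputError, eval_eric

__all__ = [
    "GroupArchetype",
    "SyntheticCohortConfig",
    "SubjectVisit",
    "CohortDataset",
    "DEFAULT_ARCHETYPES",
    "load_config",
    "sample_subject",
    "apply_effect",
    "synthesize_visit",
    "generate_cohort",
    "DegenerateNoiseError",
]

PARAM_NAMES = ("Rc", "I", "Rp", "Cp")


class DegenerateNoiseError(RuntimeError):
    """Noise so large relative to R that positivity redraws were exhausted."""


@dataclass(frozen=True)
class GroupArchetype:
    """Latent-parameter distribution and effect sizes for one group."""

    group: str
    means: dict[str, float]
    cv: dict[str, float]
    growth: dict[str, float]          # 2006 pre-B -> 2008 pre-B multipliers
    bronchodilator: dict[str, float]  # 2008 pre-B -> 2008 post-B multipliers

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if self.means.get(name, 0.0) <= 0:
                raise InvalidInputError(f"{self.group}: mean {name} must be > 0")
            if self.cv.get(name, 0.0) < 0:
                raise InvalidInputError(f"{self.group}: CV {name} must be >= 0")
            for label, mults in (("growth", self.growth), ("bronchodilator", self.bronchodilator)):
                if mults.get(name, 1.0) <= 0:
                    raise InvalidInputError(f"{self.group}: {label} multiplier {name} must be > 0")


def _default_archetypes() -> dict[str, GroupArchetype]:
    cv = {n: 0.25 for n in PARAM_NAMES}
    return {
        "H": GroupArchetype(
            group="H",
            means={"Rc": 0.35, "I": 0.0020, "Rp": 0.501, "Cp": 0.115},
            cv=dict(cv),
            growth={"Rc": 0.90, "I": 1.0, "Rp": 0.94, "Cp": 1.35},
            bronchodilator={"Rc": 0.95, "I": 1.0, "Rp": 0.82, "Cp": 1.12},
        ),
        "SAI": GroupArchetype(
            group="SAI",
            means={"Rc": 0.40, "I": 0.0018, "Rp": 0.824, "Cp": 0.045},
            cv=dict(cv),
            growth={"Rc": 0.90, "I": 1.0, "Rp": 0.73, "Cp": 1.25},
            bronchodilator={"Rc": 0.95, "I": 1.0, "Rp": 0.79, "Cp": 1.35},
        ),
    }


DEFAULT_ARCHETYPES = _default_archetypes()


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort shape, noise level and seed."""

    n_H: int = 7
    n_SAI: int = 19
    grid: tuple[float, ...] = (3.0, 5.0, 10.0, 15.0, 20.0, 25.0, 35.0)
    noise_sd_R: float = 0.01
    noise_sd_X: float = 0.01
    seed: int = 0
    archetypes: dict[str, GroupArchetype] = field(default_factory=_default_archetypes)

    def __post_init__(self) -> None:
        if self.n_H < 1 or self.n_SAI < 1:
            raise InvalidInputError("group sizes must be >= 1")
        if self.noise_sd_R < 0 or self.noise_sd_X < 0:
            raise InvalidInputError("noise sd must be >= 0")


@dataclass(frozen=True)
class SubjectVisit:
    """One measurement record: who, when, which condition, plus the data."""

    subject_id: str
    group: str
    visit: int          # 2006 | 2008
    condition: str      # "preB" | "postB"
    latent: ERICParameters | None
    spectrum: ImpedanceSpectrum


@dataclass(frozen=True)
class CohortDataset:
    """All records of a cohort; 2006 has pre-B only, 2008 pre- and post-B."""

    records: tuple[SubjectVisit, ...]

    def __len__(self) -> int:
        return len(self.records)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def select(self, group=None, visit=None, condition=None) -> list[SubjectVisit]:
        out = []
        for r in self.records:
            if group is not None and r.group != group:
                continue
            if visit is not None and r.visit != visit:
                continue
            if condition is not None and r.condition != condition:
                continue
            out.append(r)
        return out


def load_config(path) -> SyntheticCohortConfig:
    """Read a cohort config from a flat key-value text file.

    One ``key = value`` pair per line; ``#`` starts a comment. Scalar keys:
    ``n_H, n_SAI, noise_sd_R, noise_sd_X, seed``; ``grid`` takes
    space-separated Hz values. Archetype overrides use dotted keys
    ``<group>.<means|cv|growth|bronchodilator>.<param>``, e.g.
    ``SAI.means.Rp = 0.9``. Unspecified entries keep their defaults.
    """
    scalars: dict[str, object] = {}
    arch = {k: {"means": dict(v.means), "cv": dict(v.cv), "growth": dict(v.growth),
                "bronchodilator": dict(v.bronchodilator)}
            for k, v in _default_archetypes().items()}
    from pathlib import Path

    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidInputError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in ("n_H", "n_SAI", "seed"):
            scalars[key] = int(value)
        elif key in ("noise_sd_R", "noise_sd_X"):
            scalars[key] = float(value)
        elif key == "grid":
            scalars[key] = tuple(float(t) for t in value.split())
        else:
            parts = key.split(".")
            if len(parts) != 3 or parts[0] not in arch or parts[1] not in arch[parts[0]] \
                    or parts[2] not in PARAM_NAMES:
                raise InvalidInputError(f"{path}: line {lineno}: unknown key {key!r}")
            arch[parts[0]][parts[1]][parts[2]] = float(value)
    archetypes = {g: GroupArchetype(group=g, **d) for g, d in arch.items()}
    return SyntheticCohortConfig(archetypes=archetypes, **scalars)


def _substream(seed: int, *key_parts) -> np.random.Generator:
    """Per-record RNG from the cohort seed and a stable key hash."""
    crc = zlib.crc32("|".join(str(p) for p in key_parts).encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, crc]))


def sample_subject(group: str, config: SyntheticCohortConfig, rng: np.random.Generator) -> ERICParameters:
    """Draw latent eRIC constants log-normally around the group archetype.

    Parameterised so the archetype mean is the distribution's arithmetic
    mean: sigma^2 = ln(1 + CV^2), mu = ln(mean) - sigma^2 / 2. CV = 0
    returns the means exactly.
    """
    arch = config.archetypes[group]
    vals = {}
    for name in PARAM_NAMES:
        m = arch.means[name]
        c = arch.cv.get(name, 0.0)
        if c == 0.0:
            vals[name] = m
        else:
            s2 = np.log1p(c * c)
            vals[name] = float(rng.lognormal(np.log(m) - s2 / 2.0, np.sqrt(s2)))
    return ERICParameters(**vals)


def apply_effect(latent: ERICParameters, effect: str, archetype: GroupArchetype) -> ERICParameters:
    """Apply growth or bronchodilator multipliers elementwise."""
    if effect == "growth":
        mults = archetype.growth
    elif effect == "bronchodilator":
        mults = archetype.bronchodilator
    else:
        raise InvalidInputError(f"effect must be 'growth' or 'bronchodilator', got {effect!r}")
    return ERICParameters(**{n: getattr(latent, n) * mults.get(n, 1.0) for n in PARAM_NAMES})


def synthesize_visit(
    latent: ERICParameters,
    grid,
    noise_sd_R: float,
    noise_sd_X: float,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> ImpedanceSpectrum:
    """Model spectrum plus independent additive Gaussian measurement noise.

    The resistance channel is redrawn (up to ``max_redraws`` times) if any
    noisy R lands at or below zero; exhaustion raises
    :class:`DegenerateNoiseError`.
    """
    clean = eval_eric(latent, grid)
    r0 = np.asarray(clean.resistance)
    x0 = np.asarray(clean.reactance)
    for _ in range(max_redraws):
        r = r0 + rng.normal(0.0, noise_sd_R, size=r0.shape) if noise_sd_R > 0 else r0
        if np.all(r > 0):
            x = x0 + rng.normal(0.0, noise_sd_X, size=x0.shape) if noise_sd_X > 0 else x0
            return ImpedanceSpectrum(clean.frequencies, tuple(r), tuple(x))
    raise DegenerateNoiseError(
        f"{max_redraws} redraws exhausted keeping resistance positive (sd={noise_sd_R})"
    )


def generate_cohort(config: SyntheticCohortConfig | None = None) -> CohortDataset:
    """Full synthetic cohort, fully reproducible from ``config.seed``.

    Per subject: a 2006 pre-B latent draw; the growth effect gives the 2008
    pre-B latent; the bronchodilator effect on top gives 2008 post-B. One
    noisy spectrum per record.
    """
    config = config or SyntheticCohortConfig()
    records: list[SubjectVisit] = []
    roster = [("H", i) for i in range(config.n_H)] + [("SAI", i) for i in range(config.n_SAI)]
    for group, i in roster:
        sid = f"{group}{i + 1:02d}"
        arch = config.archetypes[group]
        base = sample_subject(group, config, _substream(config.seed, sid, "latent"))
        grown = apply_effect(base, "growth", arch)
        dilated = apply_effect(grown, "bronchodilator", arch)
        for visit, condition, latent in (
            (2006, "preB", base),
            (2008, "preB", grown),
            (2008, "postB", dilated),
        ):
            spec = synthesize_visit(
                latent,
                config.grid,
                config.noise_sd_R,
                config.noise_sd_X,
                _substream(config.seed, sid, visit, condition),
            )
            records.append(SubjectVisit(sid, group, visit, condition, latent, spec))
    return CohortDataset(tuple(records))
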