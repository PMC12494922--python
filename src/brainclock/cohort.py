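"""Synthetic cohorts of functional connectivity matrices.

The generator emulates the structure the downstream analyses assume: an
adult age span (17-91 y), hub ("frontoparietal"-like) connectivity that
declines with age, an expertise effect that raises hub connectivity, and
within-subject pre/post change in paired designs.

Every subject receives a latent global coupling

    g = g0 - g_age * (age - a_min)/(a_max - a_min) + g_exp * z(expertise) + eps

with eps ~ N(0, coupling_noise_sd), and the subject's FC matrix is the
linear (Lyapunov) prediction of the Hopf model at that coupling on a shared
structural connectome (a flag switches to full stochastic simulation).
Expertise is z-scored within the cohort, so domains with different raw
scales (years, hours/week, in-game performance) produce comparable effects.
Measurement noise is added on the Fisher-z transform of the off-diagonal
entries and back-transformed, keeping entries in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectome import StructuralConnectome
from .connectivity import ConnectivityMatrix, RegionalMap, compute_fc, nodal_strength
from .hopf import (
    HopfParameters,
    UnstableLinearizationError,
    linear_fc,
    simulate_hopf,
)

#: Per-domain defaults: age range (years) and expertise-score distributions.
#: Scores are in domain-native units (years of practice, hours/week of play,
#: in-game actions per minute) and are only ever compared after z-scoring.
DOMAIN_DEFAULTS = {
    "dance": {"age_range": (18.0, 50.0), "unit": "years",
              "expert": (15.0, 6.0), "non_expert": (0.5, 0.5)},
    "music": {"age_range": (22.0, 41.0), "unit": "years",
              "expert": (14.0, 5.0), "non_expert": (0.5, 0.5)},
    "visual": {"age_range": (20.0, 37.0), "unit": "years",
               "expert": (10.0, 4.0), "non_expert": (0.3, 0.3)},
    "gaming": {"age_range": (18.0, 31.0), "unit": "hours_per_week",
               "expert": (25.0, 8.0), "non_expert": (2.0, 1.5)},
    "learning": {"age_range": (20.0, 30.0), "unit": "apm",
                 "pre": (40.0, 8.0), "gain": (3.8, 2.0)},
}


@dataclass
class Subject:
    id: str
    age: float
    sex: str
    education: float
    domain: str
    group: str
    expertise_score: float
    seed: int

    def __post_init__(self):
        if self.expertise_score < 0:
            raise ValueError("expertise_score must be >= 0")
        valid = ({"pre", "post"} if self.domain == "learning"
                 else {"expert", "non_expert", "active_control"})
        if self.group not in valid:
            raise ValueError(
                f"group {self.group!r} invalid for domain {self.domain!r}"
            )


@dataclass
class Cohort:
    """Subjects paired one-to-one with their connectivity matrices."""

    subjects: list
    matrices: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.subjects) != len(self.matrices):
            raise ValueError("one matrix per subject required")
        sizes = {m.n_regions for m in self.matrices}
        if len(sizes) > 1:
            raise ValueError("all matrices must share n_regions")

    def __len__(self):
        return len(self.subjects)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def metadata(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(s) for s in self.subjects])
        return df.rename(columns={"education": "education_years"})[
            ["id", "age", "sex", "education_years", "domain", "group",
             "expertise_score"]
        ]

    def features(self) -> np.ndarray:
        """Subjects x edges matrix of vectorized upper-triangle FC."""
        from .connectivity import vectorize_fc

        return np.stack([vectorize_fc(m) for m in self.matrices])

    def strengths(self) -> np.ndarray:
        """Subjects x regions matrix of nodal strengths."""
        return np.stack([nodal_strength(m).values for m in self.matrices])

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return Cohort([self.subjects[i] for i in idx],
                      [self.matrices[i] for i in idx],
                      dict(self.provenance))


@dataclass
class CohortSpec:
    """Study conditions for one generated cohort.

    ``n_per_group`` subjects per group; unpaired designs yield expert and
    non_expert groups age/sex-matched in pairs, paired designs yield pre and
    post records for the same subjects. ``g0`` is the young-adult coupling,
    ``g_age`` the total decline across the age range, ``g_exp`` the coupling
    gain per expertise z-score.
    """

    n_per_group: int = 30
    domain: str = "learning"
    age_range: tuple = None
    paired: bool = False
    g0: float = 1.6
    g_age: float = 1.0
    g_exp: float = 0.05
    coupling_noise_sd: float = 0.12
    measurement_noise_sd: float = 0.05
    hopf_a: float = -0.05
    hopf_beta: float = 0.1
    hopf_f: float = 10.0
    use_simulation: bool = False
    sim_duration: float = 60.0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.age_range is None:
            self.age_range = DOMAIN_DEFAULTS.get(
                self.domain, {"age_range": (17.0, 91.0)}
            )["age_range"]
        lo, hi = self.age_range
        if not (17.0 <= lo < hi <= 91.0):
            raise ValueError("age range must lie within [17, 91]")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd


def _fisher_noise(fc: np.ndarray, sd: float, rng) -> np.ndarray:
    if sd == 0:
        return fc.copy()
    n = fc.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    z = np.arctanh(np.clip(fc[iu, ju], -0.999999, 0.999999))
    z = z + rng.normal(scale=sd, size=z.size)
    out = np.eye(n)
    r = np.tanh(z)
    out[iu, ju] = r
    out[ju, iu] = r
    return out


def _subject_matrix(g, spec, connectome, noise_rng, sim_seed, subject_id):
    params = HopfParameters(
        a=spec.hopf_a, f=spec.hopf_f, beta=spec.hopf_beta, G=float(g),
        duration=spec.sim_duration, seed=sim_seed,
    )
    try:
        if spec.use_simulation:
            fc = compute_fc(simulate_hopf(connectome, params))
        else:
            fc = linear_fc(connectome, params)
    except UnstableLinearizationError as err:
        raise UnstableLinearizationError(
            f"subject {subject_id}: {err}"
        ) from err
    noisy = _fisher_noise(fc.values, spec.measurement_noise_sd, noise_rng)
    return ConnectivityMatrix(noisy, "correlation", list(connectome.region_labels))


def generate_cohort(
    spec: CohortSpec, connectome: StructuralConnectome, seed: int = 0
) -> Cohort:
    """Generate a cohort under the latent-coupling model described above.

    Deterministic given (spec, connectome, seed). In unpaired designs,
    expert/non-expert pairs share age, sex and education (matched-groups
    design); in paired designs each subject contributes a pre and a post
    record that reuse the same base coupling noise, with the post record's
    expertise score raised by the training gain.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, n)
    sexes = rng.choice(["F", "M"], n)
    edu = rng.uniform(8, 22, n)
    eps = rng.normal(scale=spec.coupling_noise_sd, size=n)
    dom = DOMAIN_DEFAULTS.get(spec.domain, {})

    def draw_scores(key, size):
        mu, sd = dom.get(key, (1.0, 0.5))
        return np.clip(rng.normal(mu, sd, size), 0.0, None)

    subjects, scores, groups, base_idx = [], [], [], []
    if spec.paired:
        pre = draw_scores("pre", n)
        gain = np.clip(draw_scores("gain", n), 0.01, None)
        for k in range(n):
            for grp, sc in (("pre", pre[k]), ("post", pre[k] + gain[k])):
                subjects.append(Subject(
                    id=f"{spec.domain}_{k:03d}_{grp}", age=ages[k],
                    sex=sexes[k], education=edu[k], domain=spec.domain,
                    group=grp, expertise_score=float(sc),
                    seed=int(rng.integers(2**31 - 1)),
                ))
                scores.append(sc)
                groups.append(grp)
                base_idx.append(k)
    else:
        exp_sc = draw_scores("expert", n)
        non_sc = draw_scores("non_expert", n)
        eps_non = rng.normal(scale=spec.coupling_noise_sd, size=n)
        for k in range(n):
            for grp, sc, e in (("expert", exp_sc[k], eps[k]),
                               ("non_expert", non_sc[k], eps_non[k])):
                subjects.append(Subject(
                    id=f"{spec.domain}_{k:03d}_{grp}", age=ages[k],
                    sex=sexes[k], education=edu[k], domain=spec.domain,
                    group=grp, expertise_score=float(sc),
                    seed=int(rng.integers(2**31 - 1)),
                ))
                scores.append(sc)
                groups.append(grp)
        eps = np.stack([eps, eps_non], axis=1).ravel()
        base_idx = None

    scores = np.array(scores)
    z = _zscore(scores)
    age_of = np.array([s.age for s in subjects])
    span = hi - lo
    g = (spec.g0
         - spec.g_age * (age_of - lo) / span
         + spec.g_exp * z
         + (eps[base_idx] if spec.paired else eps))
    g = np.clip(g, 0.0, None)

    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    matrices = [
        _subject_matrix(g[i], spec, connectome, noise_rng,
                        subjects[i].seed, subjects[i].id)
        for i in range(len(subjects))
    ]
    prov = {"spec": asdict(spec), "seed": seed,
            "latent_coupling": g.tolist()}
    return Cohort(subjects, matrices, prov)


def generate_training_cohort(
    connectome: StructuralConnectome,
    n_subjects: int = 150,
    seed: int = 0,
    **overrides,
) -> Cohort:
    """Age-spanning normative cohort (17-91 y, no expertise effect).

    Convenience path for training brain clocks: ``n_subjects`` independent
    subjects with g_exp = 0 over the full adult span; all carry the
    'learning' domain label and 'pre' group.
    """
    spec = CohortSpec(
        n_per_group=max(2, n_subjects), domain="learning",
        age_range=(17.0, 91.0), paired=False, g_exp=0.0, **overrides,
    )
    rng = np.random.default_rng(seed)
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, n_subjects)
    sexes = rng.choice(["F", "M"], n_subjects)
    edu = rng.uniform(8, 22, n_subjects)
    eps = rng.normal(scale=spec.coupling_noise_sd, size=n_subjects)
    g = np.clip(spec.g0 - spec.g_age * (ages - lo) / (hi - lo) + eps, 0.0, None)
    subjects = [
        Subject(id=f"train_{k:04d}", age=ages[k], sex=sexes[k],
                education=edu[k], domain="learning", group="pre",
                expertise_score=0.0, seed=int(rng.integers(2**31 - 1)))
        for k in range(n_subjects)
    ]
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    matrices = [
        _subject_matrix(g[k], spec, connectome, noise_rng,
                        subjects[k].seed, subjects[k].id)
        for k in range(n_subjects)
    ]
    return Cohort(subjects, matrices,
                  {"spec": asdict(spec), "seed": seed,
                   "latent_coupling": g.tolist()})


def generate_term_maps(
    n_terms: int,
    connectome: StructuralConnectome,
    smoothness: float = 20.0,
    seed: int = 0,
) -> list:
    """Spatially autocorrelated stand-ins for cognitive-term association maps.

    Each map is white noise smoothed with a Gaussian distance kernel of the
    given length scale over the connectome coordinates, then standardized to
    zero mean and unit (sample) variance. ``smoothness -> 0`` approaches
    i.i.d. values.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    coords = connectome.coordinates
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    K = np.exp(-(d**2) / (2.0 * smoothness**2))
    K /= K.sum(axis=1, keepdims=True)
    maps = []
    for t in range(n_terms):
        v = K @ rng.standard_normal(connectome.n_regions)
        v = (v - v.mean()) / v.std(ddof=1)
        maps.append(RegionalMap(v, f"term_{t:03d}", list(connectome.region_labels)))
    return maps
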