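"""String-vector antibody–peptide binding model with Langmuir adsorption.

The generative model behind the simulator:

* each amino acid carries an assigned weight ``h[aa] ~ U[0, 1]`` (the
  "assigned AAWS"), so a peptide of length ``l`` becomes the vector
  ``p = (h[s_1], ..., h[s_l])`` — a position-dependent encoding;
* an antibody binding site is a unit-norm vector ``a`` of length ``l`` with
  components drawn from U[-1, 1] before scaling;
* binding association is the dot product ``y = a · p`` and translates into a
  thermodynamic association constant ``K = exp((beta0 + beta1*y)/(R*T))``,
  which at the default parameters (beta0 = 0, beta1 = R*T) is simply
  ``exp(y)``;
* the observed spot signal is the equilibrium bound fraction from Langmuir
  adsorption for a mixture of n_Ab antibodies at concentrations c (summing
  to 1):  ``S_i = sum_k c_k K_ik / (1 + sum_k c_k K_ik)``, strictly in (0, 1).

Observed profiles are log-transformed, mean-centred and scaled to unit
variance before regression; optional multiplicative Gaussian noise
``S -> S * (1 + eps)``, ``eps ~ N(0, sigma)``, is applied before the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .library import PeptideLibrary, _AA_INDEX

#: Gas constant in J/(mol*K), to the precision used throughout.
GAS_CONSTANT = 8.314472
#: Assay temperature: 25 degrees Celsius in kelvin.
ROOM_TEMP_K = 273.15 + 25


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters mapping binding association y to the
    association constant K = exp((beta0 + beta1*y) / (R*T)).

    Defaults make K = exp(y): R = 8.314472 J/(mol*K), T = 298.15 K,
    beta0 = 0 and beta1 = R*T.
    """

    R: float = GAS_CONSTANT
    T: float = ROOM_TEMP_K
    beta0: float = 0.0
    beta1: float = field(default=GAS_CONSTANT * ROOM_TEMP_K)

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")


@dataclass(frozen=True)
class AntibodyMixture:
    """A mixture of antibody binding sites with a concentration simplex.

    ``A`` is an (n_ab, l) matrix whose rows are unit-norm binding-site
    vectors; ``c`` holds non-negative concentrations summing to 1.
    """

    A: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a 2-d (n_ab, l) array")
        if c.shape != (A.shape[0],):
            raise ValueError("c must have one entry per antibody")
        norms = np.linalg.norm(A, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("antibody binding-site vectors must have unit norm")
        if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-12:
            raise ValueError("concentrations must be >= 0 and sum to 1")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "c", c)

    @property
    def n_ab(self) -> int:
        return self.A.shape[0]

    @property
    def l(self) -> int:
        return self.A.shape[1]


@dataclass(frozen=True)
class BindingProfile:
    """A signal-intensity vector over the peptides of a library.

    ``stage`` records where the vector sits in the processing chain:
    ``raw_fraction`` (Langmuir bound fractions, strictly in (0,1)),
    ``logged`` (natural log of fractions) or ``normalized`` (log,
    mean-centred, unit variance).
    """

    values: np.ndarray
    stage: str

    _STAGES = ("raw_fraction", "logged", "normalized")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("profile values must be 1-d")
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "raw_fraction" and not np.all((v > 0) & (v < 1)):
            raise ValueError("raw fractions must lie strictly in (0, 1)")
        if self.stage == "normalized":
            if abs(v.mean()) > 1e-9 or abs(v.std(ddof=1) - 1.0) > 1e-9:
                raise ValueError("normalized profile must have mean 0, sd 1")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def sample_assigned_aaws(seed: int | np.random.Generator) -> np.ndarray:
    """Draw the generative 20-vector h of per-residue binding weights,
    i.i.d. uniform on [0, 1], indexed by :data:`~aawsim.library.ALPHABET`."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=20)


def encode_peptide(sequence: str, h: np.ndarray) -> np.ndarray:
    """Encode a peptide as the vector of its residues' assigned weights.

    Position-dependent: permuting the sequence permutes the encoding.
    """
    h = np.asarray(h, dtype=float)
    if h.shape != (20,):
        raise ValueError("h must be a 20-vector")
    try:
        idx = [_AA_INDEX[ch] for ch in sequence]
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from exc
    return h[idx]


def encode_library(lib: PeptideLibrary, h: np.ndarray) -> np.ndarray:
    """Encode every peptide of a library; returns an (n_pep, l) matrix."""
    return np.vstack([encode_peptide(seq, h) for _, seq in lib])


def sample_antibody(l: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw one unit-norm binding-site vector: components i.i.d. U[-1, 1],
    then scaled to unit Euclidean norm (an all-zero draw is resampled)."""
    if l < 1:
        raise ValueError("l must be positive")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 1.0, size=l)
    while not np.any(a):
        a = rng.uniform(-1.0, 1.0, size=l)
    return a / np.linalg.norm(a)


def binding_association(a: np.ndarray, p: np.ndarray) -> float:
    """Binding association y = a · p between an antibody site and an encoded
    peptide.  Bounded by |p|_2 <= sqrt(l) via Cauchy–Schwarz."""
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    return float(a @ p)


def association_constant(y, theta: ThermoParams = ThermoParams()) -> np.ndarray | float:
    """Thermodynamic association constant K = exp((beta0 + beta1*y)/(R*T)).

    Interprets the association y as proportional to minus the standard Gibbs
    free-energy change of binding.  With default parameters K = exp(y).
    """
    expo = (theta.beta0 + theta.beta1 * np.asarray(y, dtype=float)) / (theta.R * theta.T)
    if np.any(expo > 700):  # exp overflow for float64
        raise OverflowError("association exponent out of float range")
    K = np.exp(expo)
    return float(K) if np.ndim(y) == 0 else K


def make_mixture(
    n_ab: int,
    l: int,
    seed: int | np.random.Generator,
    dominance_factor: float = 1.0,
    dominant: Optional[np.ndarray] = None,
) -> AntibodyMixture:
    """Build an antibody mixture with uniform baseline concentrations.

    Parameters
    ----------
    n_ab : int
        Total number of antibodies in the mixture (including the dominant
        one, if any).
    l : int
        Binding-site length; must match the peptide length.
    seed : int or numpy Generator
        Randomness for the binding-site draws.
    dominance_factor : float
        Weight multiplier (>= 1) for the dominant antibody; the
        concentration vector is renormalized to sum to 1 afterwards, so a
        factor f yields dominant concentration f / (f + n_ab - 1).
    dominant : array, optional
        A fixed unit-norm binding-site vector placed first in the mixture
        (the remaining n_ab - 1 sites are drawn fresh).  Required context
        for dominance experiments where one antibody is held constant.

    Returns
    -------
    AntibodyMixture
        With the dominant antibody (if any) at row 0.
    """
    if n_ab < 1:
        raise ValueError("n_ab must be >= 1")
    if dominance_factor < 1:
        raise ValueError("dominance_factor must be >= 1")
    if dominance_factor > 1 and n_ab < 2:
        raise ValueError("dominance requires at least 2 antibodies")
    rng = np.random.default_rng(seed)
    n_draw = n_ab if dominant is None else n_ab - 1
    rows = [sample_antibody(l, rng) for _ in range(n_draw)]
    if dominant is not None:
        dom = np.asarray(dominant, dtype=float)
        if dom.shape != (l,):
            raise ValueError("dominant antibody has wrong length")
        rows.insert(0, dom / np.linalg.norm(dom))
    A = np.vstack(rows)
    c = np.full(n_ab, 1.0 / n_ab)
    if dominance_factor > 1:
        c[0] *= dominance_factor
        c /= c.sum()
    return AntibodyMixture(A=A, c=c)


def simulate_signal(
    lib: PeptideLibrary,
    mix: AntibodyMixture,
    h: np.ndarray,
    theta: ThermoParams = ThermoParams(),
) -> BindingProfile:
    """Simulate raw Langmuir bound fractions for a library and a mixture.

    For every peptide i, S_i = sum_k c_k K_ik / (1 + sum_k c_k K_ik) with
    K_ik = exp((beta0 + beta1 * a_k·p_i)/(R*T)).  Each S_i lies strictly in
    (0, 1) and increases monotonically in every K_ik.
    """
    if mix.l != lib.length:
        raise ValueError(
            f"antibody length {mix.l} does not match peptide length {lib.length}"
        )
    P = encode_library(lib, h)          # (n_pep, l)
    Y = P @ mix.A.T                     # (n_pep, n_ab) associations
    K = association_constant(Y, theta)
    load = K @ mix.c                    # sum_k c_k K_ik
    S = load / (1.0 + load)
    return BindingProfile(values=S, stage="raw_fraction")


def apply_noise(
    profile: BindingProfile, sigma: float, seed: int | np.random.Generator
) -> BindingProfile:
    """Apply multiplicative Gaussian noise S -> S * (1 + eps), eps ~ N(0, sigma).

    Applied to raw fractions, before the log transform.  Any draw that would
    push a value out of the open interval (0, 1) is redrawn (essentially
    impossible at sigma = 0.01) so the logarithm stays defined.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if profile.stage != "raw_fraction":
        raise ValueError("noise applies to raw fractions only")
    if sigma == 0:
        return profile
    rng = np.random.default_rng(seed)
    S = profile.values
    out = S * (1.0 + rng.normal(0.0, sigma, size=S.shape))
    bad = (out <= 0) | (out >= 1)
    while np.any(bad):
        out[bad] = S[bad] * (1.0 + rng.normal(0.0, sigma, size=int(bad.sum())))
        bad = (out <= 0) | (out >= 1)
    return BindingProfile(values=out, stage="raw_fraction")


def normalize_signal(profile: BindingProfile) -> BindingProfile:
    """Log-transform (natural log), mean-centre and scale to unit variance.

    Raises on a constant profile (zero variance after the log).
    """
    if profile.stage != "raw_fraction":
        raise ValueError("normalization starts from raw fractions")
    logged = np.log(profile.values)
    sd = logged.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate profile: zero variance after log transform")
    return BindingProfile(values=(logged - logged.mean()) / sd, stage="normalized")


def simulate_profile(
    lib: PeptideLibrary,
    mix: AntibodyMixture,
    h: np.ndarray,
    theta: ThermoParams = ThermoParams(),
    sigma: float = 0.0,
    noise_seed: int | np.random.Generator | None = None,
) -> BindingProfile:
    """Convenience chain: simulate, add noise (pre-log), normalize."""
    raw = simulate_signal(lib, mix, h, theta)
    if sigma > 0:
        if noise_seed is None:
            raise ValueError("noise_seed required when sigma > 0")
        raw = apply_noise(raw, sigma, noise_seed)
    return normalize_signal(raw)
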