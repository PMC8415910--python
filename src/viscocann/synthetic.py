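"""Synthetic specimen populations with known composition -> mechanics maps.

The raw tissue data behind this kind of study (cyclic and relaxation
stress-stretch histories plus 11 ELISA protein concentrations per
specimen) are not publicly deposited, so this module generates stand-in
populations with a *known* ground truth: a one-term Ogden energy whose
shear modulus is driven by fibronectin content, and a two-term Prony
kernel whose weights are driven by the cellular markers (GFAP, Iba1,
MBP).  Because the causal map is recorded in a manifest, every downstream
stage -- training, cross-validation, relevance propagation -- can be
scored as a recovery experiment.

Loading protocols mirror the rheometer experiments: three compression-
tension cycles between stretches 0.85 and 1.15 at 40 um/s, then ramp-and-
hold relaxation tests (100 um/s ramps, 300 s holds) in compression and
tension, on cylindrical specimens of 5 mm height and 8 mm diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .kinematics import Ogden
from .model import FEATURES, REGIONS, CompositionVector
from .qlv import prony_from_raw, recursive_stress
from .io import SpecimenData

__all__ = [
    "CONCENTRATION_RANGES",
    "GroundTruthModel",
    "ProtocolSpec",
    "default_protocols",
    "sample_composition",
    "simulate_specimen",
    "make_dataset",
    "SyntheticDataset",
]

#: Sampling ranges (ng per mg total protein) spanning the reported
#: regional concentration windows; "loguniform" marks species whose range
#: covers well over an order of magnitude.
CONCENTRATION_RANGES = {
    "GFAP": (0.1, 1.1, "uniform"),
    "Iba1": (0.04, 0.35, "uniform"),
    "MBP": (0.02, 0.54, "uniform"),
    "HA": (0.13, 0.71, "uniform"),
    "CS": (1e-5, 9e-5, "uniform"),
    "LUM": (0.002, 0.032, "uniform"),
    "ColI": (0.0, 0.015, "uniform"),
    "ColIV": (0.0, 62.0, "uniform"),
    "ColVI": (0.0, 4.3, "uniform"),
    "FN": (1.0, 58.0, "loguniform"),
    "LAM": (0.0, 2.7, "uniform"),
}

#: Region-specific sub-ranges (fractions of the full range) reflecting the
#: reported regional trends: GFAP and Iba1 higher in cerebral white matter
#: and corpus callosum, HA higher in cerebral gray matter, etc.  Features
#: absent here use the full range in every region.
REGION_SUBRANGES = {
    "GFAP": {"CC": (0.5, 1.0), "TH": (0.4, 1.0), "cWM": (0.5, 1.0),
             "AMY": (0.0, 0.3), "cNC": (0.0, 0.3), "BS": (0.0, 0.45)},
    "Iba1": {"CR": (0.5, 1.0), "CC": (0.6, 1.0), "cWM": (0.5, 1.0),
             "C": (0.0, 0.5), "TH": (0.0, 0.5), "BG": (0.0, 0.5), "AMY": (0.0, 0.5)},
    "HA": {"C": (0.5, 1.0), "TH": (0.5, 1.0), "BG": (0.5, 1.0), "AMY": (0.5, 1.0),
           "CR": (0.0, 0.5), "CC": (0.0, 0.5), "BS": (0.0, 0.5),
           "cWM": (0.5, 1.0), "cNC": (0.0, 0.5)},
}


def _feature_standardizer():
    """Fixed per-feature affine map used by the ground-truth model.

    ``z = (log10(1 + x / xmid) - log10(2)) / s`` with ``xmid`` the range
    midpoint and ``s`` half the transformed range width, so z is roughly
    in [-1, 1] over the sampled population.  These constants are part of
    the generator definition (recorded in the manifest), independent of
    any training fold.
    """
    xmid = np.empty(len(FEATURES))
    scale = np.empty(len(FEATURES))
    for j, f in enumerate(FEATURES):
        lo, hi, _ = CONCENTRATION_RANGES[f]
        xmid[j] = 0.5 * (lo + hi)
        u_lo = np.log10(1.0 + lo / xmid[j])
        u_hi = np.log10(1.0 + hi / xmid[j])
        scale[j] = 0.5 * (u_hi - u_lo)
    return xmid, scale


_GT_XMID, _GT_SCALE = _feature_standardizer()


def _gt_z(values: np.ndarray) -> np.ndarray:
    return (np.log10(1.0 + values / _GT_XMID) - np.log10(2.0)) / _GT_SCALE


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GroundTruthModel:
    """Known composition -> constitutive-parameter map.

    The quasi-elastic energy is one-term Ogden with exponent ``ogden_alpha``
    (default -20, mimicking the strong compression-tension asymmetry of
    brain tissue) and modulus ``mu = mu0 * exp(beta_fn * z_FN)`` --
    fibronectin alone drives stiffness.  The Prony weights come from the
    cellular markers through the same sigmoid constraint mapping the model
    uses; the relaxation-time outputs are held constant (tau1 ~ 3 s,
    tau2 ~ 63 s, both visible on the protocol time scales).
    """

    mu0_kpa: float = 0.6
    beta_fn: float = 0.4
    ogden_alpha: float = -20.0
    g1_coefs: dict = field(default_factory=lambda: {"GFAP": 0.8, "Iba1": 0.5, "MBP": 0.4})
    g1_intercept: float = 0.0
    g2_coefs: dict = field(default_factory=lambda: {"MBP": 0.6, "Iba1": 0.5})
    g2_intercept: float = -0.3
    tau1_raw: float = 0.826  # tau1 = 10**(-2 + 3 s) ~ 3.0 s
    tau2_raw: float = 0.4  # tau2 = 10**(1 + 2 s) ~ 63 s
    noise_frac: float = 0.02

    def mu(self, comp: CompositionVector) -> float:
        z = _gt_z(comp.values)
        return self.mu0_kpa * float(np.exp(self.beta_fn * z[FEATURES.index("FN")]))

    def prony_raw(self, comp: CompositionVector) -> np.ndarray:
        z = dict(zip(FEATURES, _gt_z(comp.values)))
        lin1 = self.g1_intercept + sum(c * z[f] for f, c in self.g1_coefs.items())
        lin2 = self.g2_intercept + sum(c * z[f] for f, c in self.g2_coefs.items())
        return np.array([_sigmoid(lin1), _sigmoid(lin2), self.tau1_raw, self.tau2_raw])

    def prony(self, comp: CompositionVector):
        return prony_from_raw(self.prony_raw(comp))

    def energy(self, comp: CompositionVector) -> Ogden:
        return Ogden(mu=self.mu(comp), alpha=self.ogden_alpha)


@dataclass(frozen=True)
class ProtocolSpec:
    """One loading protocol of the rheometer test sequence."""

    kind: str  # cyclic | relax_compression | relax_tension
    stretch_min: float = 0.85
    stretch_max: float = 1.15
    height_mm: float = 5.0
    velocity_mm_s: float = 0.040  # 40 um/s (cyclic); 100 um/s for relaxation ramps
    cycles: int = 3
    n_cyclic: int = 250
    hold_s: float = 300.0
    ramp_hz: float = 10.0
    n_hold: int = 50

    def __post_init__(self):
        if self.kind not in ("cyclic", "relax_compression", "relax_tension"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")

    @property
    def quarter_stroke_s(self) -> float:
        """Time to traverse a 0.15 stretch span: 0.15 * H / v."""
        return (self.stretch_max - 1.0) * self.height_mm / self.velocity_mm_s

    def path(self):
        """(t, lam) sampling grid for this protocol."""
        if self.kind == "cyclic":
            return self._cyclic_path()
        return self._relaxation_path()

    def _cyclic_path(self):
        # waypoints per cycle: 1 -> min -> max -> 1; turning points are
        # sampled exactly, intervals distributed as evenly as the segment
        # durations allow (near-uniform grid).
        waypoints = [1.0]
        for _ in range(self.cycles):
            waypoints += [self.stretch_min, self.stretch_max, 1.0]
        waypoints = np.array(waypoints)
        spans = np.abs(np.diff(waypoints))
        durations = spans * self.height_mm / self.velocity_mm_s
        t_way = np.concatenate([[0.0], np.cumsum(durations)])
        n_intervals = self.n_cyclic - 1
        ideal = n_intervals * durations / durations.sum()
        counts = np.floor(ideal).astype(int)
        remainder = ideal - counts
        for idx in np.argsort(-remainder)[: n_intervals - counts.sum()]:
            counts[idx] += 1
        t_parts, lam_parts = [], []
        for k in range(len(spans)):
            ts = np.linspace(t_way[k], t_way[k + 1], counts[k] + 1)
            ls = np.linspace(waypoints[k], waypoints[k + 1], counts[k] + 1)
            if k > 0:
                ts, ls = ts[1:], ls[1:]
            t_parts.append(ts)
            lam_parts.append(ls)
        return np.concatenate(t_parts), np.concatenate(lam_parts)

    def _relaxation_path(self):
        target = self.stretch_min if self.kind == "relax_compression" else self.stretch_max
        ramp_v = 0.100  # relaxation ramps run at 100 um/s
        ramp_s = abs(target - 1.0) * self.height_mm / ramp_v
        n_ramp = int(round(ramp_s * self.ramp_hz))
        t_ramp = np.linspace(0.0, ramp_s, n_ramp + 1)
        lam_ramp = 1.0 + (target - 1.0) * t_ramp / ramp_s
        t_hold = ramp_s + np.logspace(np.log10(0.05), np.log10(self.hold_s), self.n_hold)
        lam_hold = np.full(self.n_hold, target)
        return np.concatenate([t_ramp, t_hold]), np.concatenate([lam_ramp, lam_hold])


def default_protocols() -> list[ProtocolSpec]:
    return [
        ProtocolSpec(kind="cyclic"),
        ProtocolSpec(kind="relax_compression"),
        ProtocolSpec(kind="relax_tension"),
    ]


def sample_composition(region: str, n: int, seed, *, region_effects: bool = True) -> list[CompositionVector]:
    """Draw ``n`` composition vectors for one region.

    Uniform draws within the per-feature range (log-uniform for the
    wide-range fibronectin), restricted to the region's documented
    sub-range where one is defined.  ``seed`` may be an int or a Generator.
    With ``region_effects=False`` every feature uses its full printed
    range regardless of region, making features independent across the
    population -- the setting recovery experiments need.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(int(n)):
        values = np.empty(len(FEATURES))
        for j, f in enumerate(FEATURES):
            lo, hi, law = CONCENTRATION_RANGES[f]
            sub = REGION_SUBRANGES.get(f, {}).get(region) if region_effects else None
            if sub is not None:
                lo, hi = lo + sub[0] * (hi - lo), lo + sub[1] * (hi - lo)
            if law == "loguniform":
                values[j] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
            else:
                values[j] = rng.uniform(lo, hi)
        out.append(CompositionVector(values=values, region=region))
    return out


def simulate_specimen(
    comp: CompositionVector,
    gt: GroundTruthModel,
    protocols: list[ProtocolSpec],
    seed,
    *,
    specimen_id: str = "S0",
    noise: bool = True,
) -> SpecimenData:
    """Simulate the mechanical time series of one specimen.

    Evaluates the ground-truth Ogden stress along each protocol path,
    passes it through the recursive Prony update, and adds i.i.d. Gaussian
    noise with standard deviation ``noise_frac`` times the specimen's
    noise-free peak |stress|.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    energy = gt.energy(comp)
    pset = gt.prony(comp)
    clean = {}
    for spec in protocols:
        t, lam = spec.path()
        P0 = energy.uniaxial_stress(lam)
        clean[spec.kind] = (t, lam, recursive_stress(t, P0, pset).P)
    peak = max(np.max(np.abs(P)) for _, _, P in clean.values())
    series = {}
    for kind, (t, lam, P) in clean.items():
        if noise and gt.noise_frac > 0.0:
            P = P + rng.normal(0.0, gt.noise_frac * peak, size=P.shape)
        series[kind] = (t, lam, P)
    return SpecimenData(specimen_id=specimen_id, composition=comp, protocols=series)


@dataclass
class SyntheticDataset:
    specimens: list
    manifest: dict


def make_dataset(
    n_specimens: int = 10,
    seed: int = 7,
    *,
    regions: tuple = REGIONS,
    gt: GroundTruthModel | None = None,
    protocols: list[ProtocolSpec] | None = None,
    noise: bool = True,
    region_effects: bool = True,
) -> SyntheticDataset:
    """Generate a specimen population with a ground-truth manifest.

    Specimens are assigned to regions round-robin.  The manifest records
    the generator seed, the ground-truth coefficients, and every
    specimen's composition and constitutive parameters, which suffices to
    recompute each noise-free curve bit-identically.
    """
    gt = gt or GroundTruthModel()
    protocols = protocols or default_protocols()
    rng = np.random.default_rng(seed)
    specimens = []
    entries = []
    for k in range(n_specimens):
        region = regions[k % len(regions)]
        comp = sample_composition(region, 1, rng, region_effects=region_effects)[0]
        sid = f"{region}-{k:02d}"
        spec = simulate_specimen(comp, gt, protocols, rng, specimen_id=sid, noise=noise)
        specimens.append(spec)
        entries.append(
            {
                "specimen_id": sid,
                "region": region,
                "composition": comp.as_dict(),
                "mu_kpa": gt.mu(comp),
                "prony_raw": gt.prony_raw(comp).tolist(),
                "prony_v": gt.prony(comp).v.tolist(),
            }
        )
    manifest = {
        "generator": "viscocann.synthetic.make_dataset",
        "seed": int(seed),
        "noise": bool(noise),
        "ground_truth": {
            "mu0_kpa": gt.mu0_kpa,
            "beta_fn": gt.beta_fn,
            "ogden_alpha": gt.ogden_alpha,
            "g1_coefs": gt.g1_coefs,
            "g1_intercept": gt.g1_intercept,
            "g2_coefs": gt.g2_coefs,
            "g2_intercept": gt.g2_intercept,
            "tau1_raw": gt.tau1_raw,
            "tau2_raw": gt.tau2_raw,
            "noise_frac": gt.noise_frac,
            "feature_standardizer": {"xmid": _GT_XMID.tolist(), "scale": _GT_SCALE.tolist()},
        },
        "specimens": entries,
    }
    return SyntheticDataset(specimens=specimens, manifest=manifest)
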