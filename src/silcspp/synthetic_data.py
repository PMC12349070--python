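"""Synthetic feeding-experiment data with full ground truth.

The generator emulates the statistical and kinetic structure of a
labeled-precursor feeding study: an exogenous pool of a 13C3-labeled precursor
is taken up by the seedlings and propagates through a biotransformation
pathway as successive transient accumulation waves, while native (unlabeled)
pools stay near steady state.  Each compound is observed as one or more
negative-mode LC-MS ions (molecular ion, acetate adduct, homodimer), each as a
light feature plus heavy isotopologue features shifted by multiples of
3 x 1.003355 Da.

The labeled pools follow a linear first-order compartment cascade (solved
exactly with a matrix exponential), which keeps every stage checkable against
closed-form Bateman solutions.  Doubly labeled (13C6) species of two-moiety
conjugates are modeled by binomial assembly from the per-site labeled
fraction, reproducing the delayed appearance of doubly labeled conjugates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.special import comb

from . import chem
from .cspp_network import FeatureIon, match_pair
from .features import DEFAULT_TIMES_H, SampleDesign, group_by_coelution
from .sil_trace import Multiplet

__all__ = [
    "CompoundSpec",
    "PathwayEdge",
    "PathwaySpec",
    "KineticsResult",
    "SyntheticTruth",
    "simulate_kinetics",
    "emit_feature_table",
    "builtin_flax_spec",
    "chain_spec",
    "wave_profiles",
]

#: Ion response of each further adduct of a compound relative to its first.
SECONDARY_ADDUCT_FACTOR = 0.15

#: Relative drift of the native pools over the time course (quasi-steady).
NATIVE_DRIFT = 0.05


@dataclass(frozen=True)
class CompoundSpec:
    """One pathway compound and how it ionizes.

    ``moieties`` is the number of precursor-derived three-carbon moieties the
    molecule can carry (0 = fully native compound, never labeled); ``decay``
    is a first-order loss rate into an unobserved sink (h^-1).
    """

    name: str
    formula: str
    moieties: int
    rt: float
    adducts: tuple[str, ...] = ("[M-H]-",)
    response: float = 1.0
    native_level: float = 2e4
    decay: float = 0.02


@dataclass(frozen=True)
class PathwayEdge:
    """A first-order conversion; ``conversion`` names a ruleset rule (used to
    validate elution order) or None for an unguided kinetic transfer."""

    substrate: str
    product: str
    rate: float
    conversion: str | None = None


@dataclass(frozen=True)
class PathwaySpec:
    compounds: tuple[CompoundSpec, ...]
    edges: tuple[PathwayEdge, ...]
    precursor: str
    uptake_rate: float = 8.0   # medium -> precursor pool, h^-1
    dose: float = 1e6          # administered labeled precursor (intensity units)

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound names")
        if self.precursor not in names:
            raise ValueError("precursor not among compounds")
        for e in self.edges:
            if e.rate <= 0:
                raise ValueError(f"rate must be positive on edge {e.substrate}->{e.product}")
            if e.substrate not in names or e.product not in names:
                raise ValueError(f"edge references unknown compound: {e}")
        graph = nx.DiGraph((e.substrate, e.product) for e in self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("pathway graph must be acyclic")

    def compound(self, name: str) -> CompoundSpec:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)

    def validate_elution_orders(self, ruleset: chem.Ruleset | None = None) -> None:
        """Check every rule-labeled edge against the rule's elution order."""
        if ruleset is None:
            ruleset = chem.builtin_ruleset()
        for e in self.edges:
            if e.conversion is None:
                continue
            rule = ruleset.lookup(e.conversion)
            rt_s = self.compound(e.substrate).rt
            rt_p = self.compound(e.product).rt
            if rule.elution_order == 1 and not rt_p < rt_s:
                raise ValueError(
                    f"{e.substrate}->{e.product}: rule {rule.short} requires the "
                    f"product to elute earlier (got {rt_p} vs {rt_s})"
                )
            if rule.elution_order == 2 and not rt_p > rt_s:
                raise ValueError(
                    f"{e.substrate}->{e.product}: rule {rule.short} requires the "
                    f"product to elute later (got {rt_p} vs {rt_s})"
                )


@dataclass(frozen=True)
class KineticsResult:
    """Exact solution of the labeled-moiety cascade.

    ``labeled[i, t]`` is the labeled moiety-equivalent pool of compound i;
    ``medium`` the remaining exogenous precursor; ``sink`` degraded label.
    ``native[i, t]`` is the quasi-steady native pool (molecules).
    """

    spec: PathwaySpec
    times: np.ndarray
    compounds: tuple[str, ...]
    labeled: np.ndarray
    native: np.ndarray
    medium: np.ndarray
    sink: np.ndarray

    def index(self, name: str) -> int:
        return self.compounds.index(name)

    def labeled_fraction(self, name: str) -> np.ndarray:
        """Per-moiety-site labeled fraction p(t) of one compound."""
        c = self.spec.compound(name)
        if c.moieties == 0:
            return np.zeros_like(self.times)
        x = self.labeled[self.index(name)]
        site_pool = x + c.moieties * self.native[self.index(name)]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(site_pool > 0, x / site_pool, 0.0)

    def total_molecules(self, name: str) -> np.ndarray:
        c = self.spec.compound(name)
        x = self.labeled[self.index(name)]
        extra = x / c.moieties if c.moieties else 0.0
        return self.native[self.index(name)] + extra

    def class_abundance(self, name: str, k: int, sites: int | None = None) -> np.ndarray:
        """Abundance of the isotopologue class carrying k labeled moieties,
        by binomial assembly over ``sites`` labeled-moiety sites (defaults to
        the compound's moiety count)."""
        c = self.spec.compound(name)
        if sites is None:
            sites = c.moieties
        if k > sites:
            return np.zeros_like(self.times)
        p = self.labeled_fraction(name)
        weight = comb(sites, k, exact=True) * p**k * (1 - p) ** (sites - k)
        return self.total_molecules(name) * weight

    def mass_balance_error(self) -> float:
        """Max relative deviation of medium + pools + sink from the dose."""
        total = self.labeled.sum(axis=0) + self.medium + self.sink
        return float(np.abs(total - self.spec.dose).max() / self.spec.dose)


def simulate_kinetics(spec: PathwaySpec, times: Sequence[float] | None = None) -> KineticsResult:
    """Solve the labeled cascade exactly at the given sampling times.

    Compartments: exogenous medium -> precursor -> pathway edges -> sink.  The
    label dose sits in the medium at t=0 (the seedling pools start empty), so
    the t=0 sample is unlabeled, as in a pre-feeding baseline.
    """
    if times is None:
        times = DEFAULT_TIMES_H
    times = np.asarray(times, float)
    if times[0] != 0:
        raise ValueError("times must include 0 (pre-feeding baseline)")
    names = tuple(c.name for c in spec.compounds)
    n = len(names)
    idx = {name: i + 1 for i, name in enumerate(names)}  # 0 = medium, n+1 = sink
    dim = n + 2
    a = np.zeros((dim, dim))
    a[0, 0] = -spec.uptake_rate
    a[idx[spec.precursor], 0] = spec.uptake_rate
    for e in spec.edges:
        a[idx[e.product], idx[e.substrate]] += e.rate
        a[idx[e.substrate], idx[e.substrate]] -= e.rate
    for c in spec.compounds:
        if c.decay:
            a[dim - 1, idx[c.name]] += c.decay
            a[idx[c.name], idx[c.name]] -= c.decay
    x0 = np.zeros(dim)
    x0[0] = spec.dose
    states = np.array([expm(a * t) @ x0 for t in times]).T  # (dim, T)
    t_max = times.max() if times.max() > 0 else 1.0
    native = np.array(
        [c.native_level * (1 + NATIVE_DRIFT * times / t_max) for c in spec.compounds]
    )
    return KineticsResult(
        spec=spec,
        times=times,
        compounds=names,
        labeled=states[1 : n + 1],
        native=native,
        medium=states[0],
        sink=states[dim - 1],
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic feature table."""

    clean_features: pd.DataFrame
    meta: pd.DataFrame  # feature id -> compound, adduct, k
    multiplets: tuple[Multiplet, ...]
    multiplet_links: frozenset[tuple[str, int, str]]  # (light, k, heavy)
    edges: frozenset[tuple[str, str, str]]            # (substrate, product, short)

    def peak_times(self, kinetics: KineticsResult) -> dict[str, float]:
        """Expected (noise-free) peak time of every heavy feature."""
        out = {}
        for row in self.meta.itertuples():
            if row.k == 0:
                continue
            abundance = kinetics.class_abundance(row.compound, int(row.k), int(row.sites))
            out[row.id] = float(kinetics.times[np.argmax(abundance)])
        return out


def _feature_id(compound: str, adduct: str, k: int) -> str:
    slug = adduct.strip("[]-").replace("+", "")
    return f"{compound}|{slug}|k{k}"


def emit_feature_table(
    spec: PathwaySpec,
    kinetics: KineticsResult | None = None,
    design: SampleDesign | None = None,
    cv: float = 0.2,
    mz_sigma: float = 0.0003,
    rt_jitter: float = 0.02,
    lod: float = 50.0,
    seed: int = 0,
    mass_tol: float = 0.002,
    rt_tol: float = 0.1,
    ruleset: chem.Ruleset | None = None,
) -> tuple[pd.DataFrame, SampleDesign, SyntheticTruth]:
    """Render the kinetics as a noisy LC-MS feature table plus ground truth.

    Noise model: multiplicative lognormal on intensities (coefficient of
    variation ``cv``), Gaussian on m/z (``mz_sigma`` Da), uniform jitter on RT
    (+/- ``rt_jitter`` min); intensities below ``lod`` are zeroed.  The same
    seed always yields the identical table.

    Ground truth is derived from the noise-free table: planted multiplet links
    and the planted CSPP edge set (the SIL-restricted all-pairs rule matching
    at nominal m/z and RT, same-compound ion pairs excluded).
    """
    if kinetics is None:
        kinetics = simulate_kinetics(spec)
    if design is None:
        design = SampleDesign.default(tuple(kinetics.times))
    if ruleset is None:
        ruleset = chem.builtin_ruleset()
    rng = np.random.default_rng(seed)
    sigma_log = float(np.sqrt(np.log1p(cv**2)))
    time_of = dict(zip(design.table["sample"], design.table["time_h"]))
    time_index = {t: i for i, t in enumerate(kinetics.times)}

    rows = []
    meta_rows = []
    for compound in spec.compounds:
        neutral = chem.parse_formula(compound.formula)
        for a_i, adduct_name in enumerate(compound.adducts):
            adduct = chem.ADDUCTS[adduct_name]
            sites = adduct.multimer * compound.moieties
            response = compound.response * SECONDARY_ADDUCT_FACTOR**a_i
            for k in range(sites + 1):
                clean = kinetics.class_abundance(compound.name, k, sites) * response
                if clean.max() < lod:
                    continue
                fid = _feature_id(compound.name, adduct_name, k)
                mz_clean = chem.ion_mz(neutral.with_labeled(3 * k), adduct)
                intensities = {}
                clean_intensities = {}
                for sample in design.samples:
                    base = clean[time_index[time_of[sample]]]
                    noisy = base * rng.lognormal(0.0, sigma_log)
                    intensities[sample] = noisy if noisy >= lod else 0.0
                    clean_intensities[sample] = base if base >= lod else 0.0
                rows.append(
                    {
                        "id": fid,
                        "mz": mz_clean + rng.normal(0.0, mz_sigma),
                        "rt": compound.rt + rng.uniform(-rt_jitter, rt_jitter),
                        **intensities,
                    }
                )
                meta_rows.append(
                    {
                        "id": fid,
                        "compound": compound.name,
                        "adduct": adduct_name,
                        "k": k,
                        "sites": sites,
                        "mz_clean": mz_clean,
                        "rt_clean": compound.rt,
                        **{f"clean:{s}": v for s, v in clean_intensities.items()},
                    }
                )

    features = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows)
    clean = pd.DataFrame(
        {
            "id": meta["id"],
            "mz": meta["mz_clean"],
            "rt": meta["rt_clean"],
            **{s: meta[f"clean:{s}"].to_numpy() for s in design.samples},
        }
    )

    # Planted multiplets: per (compound, adduct), the light ion plus heavies.
    multiplets = []
    links = set()
    clean_groups = group_by_coelution(clean, rt_tol)
    group_of = clean_groups.to_dict()
    for (compound_name, adduct_name), sub in meta.groupby(["compound", "adduct"], sort=False):
        sub = sub.sort_values("k")
        if sub.iloc[0]["k"] != 0 or len(sub) < 2:
            continue
        light = sub.iloc[0]["id"]
        members = tuple((int(r.k), str(r.id), 0.0) for r in sub.iloc[1:].itertuples())
        multiplets.append(Multiplet(str(light), int(group_of[light]), members))
        links.update((light, k, fid) for k, fid, _ in members)

    # Planted CSPP edges: SIL-restricted all-pairs matching on clean values.
    member_meta = {
        str(r.id): (str(r.compound), str(r.adduct))
        for r in meta.itertuples()
        if any(str(r.id) in m.feature_ids for m in multiplets)
    }
    ions = [
        FeatureIon(str(r.id), float(r.mz_clean), float(r.rt_clean))
        for r in meta.itertuples()
        if str(r.id) in member_meta
    ]
    edges = set()
    for i in range(len(ions)):
        for j in range(i + 1, len(ions)):
            if member_meta[ions[i].id] == member_meta[ions[j].id]:
                continue
            for hit in match_pair(ions[i], ions[j], ruleset, mass_tol):
                edges.add((hit.substrate_id, hit.product_id, hit.conversion.short))

    truth = SyntheticTruth(
        clean_features=clean,
        meta=meta.drop(columns=[c for c in meta.columns if c.startswith("clean:")]),
        multiplets=tuple(multiplets),
        multiplet_links=frozenset(links),
        edges=frozenset(edges),
    )
    return features, design, truth


def builtin_flax_spec() -> PathwaySpec:
    """A packaged flax-seedling-like pathway: the fed precursor branches into
    tartaric/glucaric/glucose ester conjugates culminating in dicaffeoyl
    tartaric acid (chicoric acid), and into the coniferin-derived
    dilignol/lignan branch.  Retention times follow the reference compound
    inventory; moiety counts encode how many precursor-derived units each
    conjugate carries."""
    c = CompoundSpec
    compounds = (
        c("coumaric_acid", "C9H8O3", 1, 9.6, ("[M-H]-",), 1.0, 5e4, 0.05),
        c("coumaric_acid_glucoside", "C15H18O8", 1, 6.9, ("[M+Ac-H]-", "[2M-H]-"), 1.0, 3e4),
        c("coumaroyl_glucose", "C15H18O8", 1, 8.8, ("[M-H]-",), 1.0, 2e4),
        c("coumaroyl_tartaric_1", "C13H12O8", 1, 3.1, ("[M-H]-",), 1.0, 2e4),
        c("coumaroyl_tartaric_2", "C13H12O8", 1, 3.5, ("[M-H]-",), 1.0, 2e4),
        c("coumaroyl_glucaric", "C15H16O10", 1, 3.6, ("[M-H]-",), 1.0, 1.5e4),
        c("caffeic_acid_glucoside", "C15H18O9", 1, 6.2, ("[M-H]-",), 1.0, 2e4),
        c("ferulic_acid_glucoside", "C16H20O9", 1, 8.5, ("[M+Ac-H]-",), 1.0, 2e4, 0.05),
        c("dihydrocoumaroyl_glucose", "C15H20O8", 1, 8.5, ("[M-H]-",), 1.0, 1.5e4),
        c("coniferin", "C16H22O8", 1, 8.9, ("[M+Ac-H]-",), 1.0, 3e4),
        c("glucoside_glucose_ester", "C21H28O13", 0, 6.2, ("[M+Ac-H]-",), 1.0, 3e4),
        c("dicoumaroyl_tartaric_1", "C22H18O10", 2, 11.4, ("[M-H]-",), 1.0, 8e3, 0.08),
        c("dicoumaroyl_tartaric_2", "C22H18O10", 2, 12.6, ("[M-H]-",), 1.0, 8e3, 0.05),
        c("coumaroyl_caffeoyl_tartaric", "C22H18O11", 2, 10.3, ("[M-H]-",), 1.0, 4e3, 0.08),
        c("chicoric_acid", "C22H18O12", 2, 9.4, ("[M-H]-",), 1.0, 2e5, 0.0),
        c("g8o4g_glucoside", "C26H34O12", 2, 10.7, ("[M+Ac-H]-",), 1.0, 1e4),
        c("ddc_glucoside", "C26H32O11", 2, 12.6, ("[M+Ac-H]-",), 1.0, 1e4),
        c("pinoresinol_diglucoside", "C32H42O16", 2, 11.4, ("[M+Ac-H]-",), 1.0, 1e4, 0.04),
        c("lariciresinol_diglucoside_1", "C32H44O16", 2, 9.0, ("[M+Ac-H]-",), 1.0, 1e4, 0.0),
        c("lariciresinol_diglucoside_2", "C32H44O16", 2, 10.5, ("[M+Ac-H]-",), 1.0, 1e4, 0.0),
        c("lariciresinol_glucoside", "C26H34O11", 2, 12.9, ("[M-H]-",), 1.0, 8e3, 0.0),
        c("pinoresinol_glucoside", "C26H32O11", 2, 13.9, ("[M-H]-",), 1.0, 8e3, 0.02),
    )
    e = PathwayEdge
    edges = (
        e("coumaric_acid", "coumaric_acid_glucoside", 0.10, "Hex"),
        e("coumaric_acid", "coumaroyl_glucose", 0.06, "Hex"),
        e("coumaric_acid", "coumaroyl_tartaric_1", 0.05, "Tar"),
        e("coumaric_acid", "coumaroyl_tartaric_2", 0.04, "Tar"),
        e("coumaric_acid", "coumaroyl_glucaric", 0.04, "GlcA"),
        e("coumaric_acid", "coniferin", 0.06, None),
        e("coumaric_acid_glucoside", "caffeic_acid_glucoside", 0.25, "Oxy"),
        e("caffeic_acid_glucoside", "ferulic_acid_glucoside", 0.15, "Met"),
        e("coumaroyl_glucose", "dihydrocoumaroyl_glucose", 0.12, "Red.neg"),
        e("coumaroyl_tartaric_1", "dicoumaroyl_tartaric_1", 0.15, "Cou"),
        e("coumaroyl_tartaric_2", "dicoumaroyl_tartaric_2", 0.12, "Cou"),
        e("coumaroyl_tartaric_1", "coumaroyl_caffeoyl_tartaric", 0.10, "Caf"),
        e("dicoumaroyl_tartaric_1", "coumaroyl_caffeoyl_tartaric", 0.10, "Oxy"),
        e("coumaroyl_caffeoyl_tartaric", "chicoric_acid", 0.12, "Oxy"),
        e("coniferin", "g8o4g_glucoside", 0.15, "Gun"),
        e("coniferin", "ddc_glucoside", 0.18, "condGun"),
        e("ddc_glucoside", "pinoresinol_diglucoside", 0.20, "Hex"),
        e("pinoresinol_diglucoside", "lariciresinol_diglucoside_1", 0.10, "Red.neg"),
        e("pinoresinol_diglucoside", "lariciresinol_diglucoside_2", 0.08, "Red.neg"),
        e("pinoresinol_diglucoside", "pinoresinol_glucoside", 0.10, None),
        e("lariciresinol_diglucoside_1", "lariciresinol_glucoside", 0.10, None),
        e("lariciresinol_diglucoside_2", "lariciresinol_glucoside", 0.06, None),
    )
    spec = PathwaySpec(compounds, edges, precursor="coumaric_acid")
    spec.validate_elution_orders()
    return spec


def chain_spec(rates: Sequence[float] = (0.8, 0.5, 0.3, 0.2, 0.12)) -> PathwaySpec:
    """A linear chain with staggered, distinct rates — the minimal design for
    successive accumulation waves (closed-form Bateman kinetics)."""
    n = len(rates)
    compounds = tuple(
        CompoundSpec(f"c{i}", "C9H8O3", 1, 10.0 - i, ("[M-H]-",), 1.0, 1e4, 0.0)
        for i in range(n)
    )
    edges = tuple(
        PathwayEdge(f"c{i}", f"c{i + 1}", rates[i + 1], None) for i in range(n - 1)
    )
    # outflow of the last compartment keeps all peaks transient
    compounds = compounds[:-1] + (
        CompoundSpec(f"c{n - 1}", "C9H8O3", 1, 10.0 - (n - 1), ("[M-H]-",), 1.0, 1e4, rates[-1] / 2),
    )
    return PathwaySpec(compounds, edges, precursor="c0", uptake_rate=rates[0] * 10)


def wave_profiles(
    peak_times: Sequence[float] = (4, 6, 8, 12, 36),
    n_per_wave: int = 6,
    times: Sequence[float] = DEFAULT_TIMES_H,
    n_replicates: int = 3,
    cv: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature mean time profiles in planted accumulation waves.

    Every feature in wave w follows the same transient pulse shape peaking at
    ``peak_times[w]`` (a gamma-like rise-and-decay), with per-replicate
    multiplicative lognormal noise of the given CV averaged over replicates —
    the profile construction used for clustering.  Returns (profiles indexed
    by feature id with one column per time, wave labels).
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, float)
    sigma_log = float(np.sqrt(np.log1p(cv**2)))
    shape_power = 3.0
    rows = {}
    labels = {}
    for w, tp in enumerate(peak_times):
        shape = (times / tp) ** shape_power * np.exp(shape_power * (1 - times / tp))
        for i in range(n_per_wave):
            fid = f"w{w}_{i}"
            scale = rng.lognormal(np.log(1e4), 0.5)
            reps = scale * shape * rng.lognormal(0.0, sigma_log, size=(n_replicates, times.size))
            rows[fid] = reps.mean(axis=0)
            labels[fid] = w
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=times)
    profiles.columns.name = "time_h"
    return profiles, pd.Series(labels, name="wave")
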