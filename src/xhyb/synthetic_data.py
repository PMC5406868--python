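"""Synthetic probe-level data with the structure a cross-species study assumes.

The generator emulates a two-genotype dehydration experiment assayed on a
heterologous oligonucleotide array:

* a chip layout of probe sets, each interrogated by several PM probe pairs
  (11 by default, the layout of the array family this models);
* genomic-DNA hybridisations in which sequence divergence appears as
  Bernoulli probe-pair dropout — a probe either binds the target genome or
  reports optical background;
* RNA hybridisations over a water-sufficient / water-limited / recovery
  design (3, 4 and 3 replicates per genotype by default), with planted
  differentially expressed genes, a small cross-genotype DEG overlap,
  a responsive/perturbed split at recovery, and co-fluctuating modules;
* a :class:`SimulationTruth` record of everything planted, for recovery
  testing downstream.

Probe affinities are multiplicative (lognormal) and shared between the two
genotypes, mimicking near-identical genomes; they cancel in the additive
log2 row+column model that median polish fits.  Module co-fluctuation is a
per-sample latent factor whose scale is tied to the measurement noise, so
the noise-free limit reproduces planted effects exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chipmodel import (
    ChipLayout,
    ProbeIntensityMatrix,
    SampleSheet,
    ValidationError,
)

DEFAULT_GENOTYPES = ("DipC", "TN")

#: replicate structure of the emulated design: (treatment, n_replicates)
DEFAULT_DESIGN = (
    ("water_sufficient", 3),
    ("water_limited", 4),
    ("recovery", 3),
)


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator.

    ``sets`` is indexed by probe_set_id with columns ``baseline_log2`` and
    ``module_id`` (-1 for none).  ``de`` is long-format with one row per
    (probe_set_id, genotype) DE assignment: ``de_status`` (up/down),
    ``log2fc`` (signed) and ``response_class`` (responsive/perturbed).
    ``probes`` is long-format per (probe_id, genotype) with ``affinity``
    and ``binds``; it is filled by :func:`simulate_gdna` (or with ideal
    full binding the first time :func:`simulate_rna` needs it).
    """

    genotypes: tuple[str, ...]
    sets: pd.DataFrame
    de: pd.DataFrame
    probes: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def de_sets(self, genotype: str) -> set[str]:
        d = self.de[self.de["genotype"] == genotype]
        return set(d["probe_set_id"])

    def de_frame(self, genotype: str) -> pd.DataFrame:
        return self.de[self.de["genotype"] == genotype].set_index("probe_set_id")

    def module_members(self, module_id: int) -> list[str]:
        s = self.sets
        return list(s.index[s["module_id"] == module_id])

    def to_tsv(self, path) -> None:
        out = self.de.merge(
            self.sets[["module_id"]], left_on="probe_set_id", right_index=True
        )
        out = out.sort_values(["probe_set_id", "genotype"], kind="mergesort")
        cols = ["probe_set_id", "genotype", "de_status", "log2fc",
                "response_class", "module_id"]
        out.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


def simulate_layout(n_sets: int, pairs_per_set: int = 11, seed: int = 0) -> ChipLayout:
    """Deterministic synthetic chip layout of ``n_sets`` x ``pairs_per_set``."""
    if n_sets < 1 or pairs_per_set < 1:
        raise ValidationError("n_sets and pairs_per_set must be >= 1")
    width = max(5, len(str(n_sets)))
    set_ids = np.array([f"PS{i:0{width}d}" for i in range(n_sets)])
    table = pd.DataFrame(
        {
            "probe_id": [
                f"{s}_p{j:02d}" for s in set_ids for j in range(pairs_per_set)
            ],
            "probe_set_id": np.repeat(set_ids, pairs_per_set),
            "pair_index": np.tile(np.arange(pairs_per_set), n_sets),
        }
    )
    return ChipLayout(table)


def simulate_sample_sheet(
    genotypes=DEFAULT_GENOTYPES, design=DEFAULT_DESIGN
) -> SampleSheet:
    """Sample sheet for the default design (3 / 4 / 3 replicates per genotype)."""
    rows = []
    for g in genotypes:
        for treatment, n in design:
            for r in range(1, n + 1):
                rows.append(
                    {
                        "sample_id": f"{g}.{treatment}.rep{r}",
                        "genotype": g,
                        "treatment": treatment,
                        "replicate": r,
                        "excluded": False,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------


def simulate_truth(
    layout: ChipLayout,
    n_de_per_genotype: int,
    n_common_de: int,
    frac_responsive: float = 0.75,
    log2fc_range: tuple[float, float] = (1.1, 2.0),
    n_modules: int = 0,
    module_size: int = 10,
    genotypes=DEFAULT_GENOTYPES,
    baseline_log2_mean: float = 10.0,
    baseline_log2_sd: float = 1.0,
    seed: int = 0,
) -> SimulationTruth:
    """Plant DE genes, response classes and co-expression modules.

    Exactly ``n_common_de`` probe sets are DE in every genotype with a shared
    sign and magnitude; genotype-specific DE sets are disjoint between
    genotypes so the planted overlap is exact.  Per genotype, exactly
    ``round(frac_responsive * n_de_per_genotype)`` DE sets are responsive
    (their stress effect vanishes at recovery); the rest are perturbed
    (the effect persists).  Modules are blocks of ``module_size`` non-DE
    sets that co-fluctuate across samples.
    """
    n_sets = layout.n_sets
    genotypes = tuple(genotypes)
    if not 0 <= n_common_de <= n_de_per_genotype <= n_sets:
        raise ValidationError(
            "need 0 <= n_common_de <= n_de_per_genotype <= number of probe sets"
        )
    if not 0.0 <= frac_responsive <= 1.0:
        raise ValidationError("frac_responsive must be in [0, 1]")
    n_specific = n_de_per_genotype - n_common_de
    needed = n_common_de + n_specific * len(genotypes) + n_modules * module_size
    if needed > n_sets:
        raise ValidationError(
            f"infeasible: {needed} distinct probe sets required, layout has {n_sets}"
        )
    lo, hi = log2fc_range
    if lo <= 0 or hi < lo:
        raise ValidationError("log2fc_range must satisfy 0 < lo <= hi")

    rng = np.random.default_rng(seed)
    set_ids = np.asarray(layout.probe_set_ids)
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, n_sets)

    picked = rng.choice(n_sets, size=needed, replace=False)
    common = set_ids[picked[:n_common_de]]
    pos = n_common_de
    specific = {}
    for g in genotypes:
        specific[g] = set_ids[picked[pos : pos + n_specific]]
        pos += n_specific
    module_sets = set_ids[picked[pos:]]

    module_id = pd.Series(-1, index=set_ids, dtype=int)
    for m in range(n_modules):
        members = module_sets[m * module_size : (m + 1) * module_size]
        module_id.loc[members] = m

    # common genes share direction and magnitude across genotypes
    common_lfc = rng.uniform(lo, hi, n_common_de) * rng.choice(
        [-1.0, 1.0], n_common_de
    )
    n_resp = round(frac_responsive * n_de_per_genotype)
    rows = []
    for g in genotypes:
        ids = np.concatenate([common, specific[g]])
        lfc = np.concatenate(
            [
                common_lfc,
                rng.uniform(lo, hi, n_specific)
                * rng.choice([-1.0, 1.0], n_specific),
            ]
        )
        resp_idx = rng.choice(n_de_per_genotype, size=n_resp, replace=False)
        cls = np.full(n_de_per_genotype, "perturbed", dtype=object)
        cls[resp_idx] = "responsive"
        for i in range(n_de_per_genotype):
            rows.append(
                {
                    "probe_set_id": ids[i],
                    "genotype": g,
                    "de_status": "up" if lfc[i] > 0 else "down",
                    "log2fc": lfc[i],
                    "response_class": cls[i],
                }
            )
    de = pd.DataFrame(
        rows, columns=["probe_set_id", "genotype", "de_status", "log2fc",
                       "response_class"]
    )
    sets = pd.DataFrame(
        {"baseline_log2": baseline, "module_id": module_id.values}, index=set_ids
    )
    sets.index.name = "probe_set_id"
    params = {
        "seed": seed,
        "n_de_per_genotype": n_de_per_genotype,
        "n_common_de": n_common_de,
        "n_responsive_per_genotype": n_resp,
        "frac_responsive": frac_responsive,
        "log2fc_range": [lo, hi],
        "n_modules": n_modules,
        "module_size": module_size,
    }
    return SimulationTruth(genotypes=genotypes, sets=sets, de=de, params=params)


# ---------------------------------------------------------------------------
# gDNA hybridisation
# ---------------------------------------------------------------------------


def simulate_gdna(
    layout: ChipLayout,
    bind_prob,
    signal_log2_mean: float = 10.0,
    signal_log2_sd: float = 1.0,
    background_log2_mean: float = 6.0,
    background_log2_sd: float = 1.0,
    affinity_log2_sd: float = 0.5,
    seed: int = 0,
    truth: SimulationTruth | None = None,
    genotypes=None,
) -> ProbeIntensityMatrix:
    """One gDNA hybridisation column per genotype.

    ``bind_prob`` is a float (shared) or mapping genotype -> probability that
    a probe pair binds the genotype's genomic DNA.  A single uniform draw per
    probe pair is shared across genotypes, so genotypes with equal
    probabilities have identical binding sets — the near-identical-genome
    regime in which the two masks overlap almost completely.  Binding probes
    draw intensity = affinity x lognormal signal; non-binding probes draw
    lognormal background.  Binding flags and affinities are recorded in
    ``truth.probes`` when a truth object is supplied.
    """
    if genotypes is None:
        genotypes = truth.genotypes if truth is not None else DEFAULT_GENOTYPES
    genotypes = tuple(genotypes)
    if not isinstance(bind_prob, dict):
        bind_prob = {g: float(bind_prob) for g in genotypes}
    for g, p in bind_prob.items():
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"bind_prob for {g!r} must be in (0, 1], got {p}")
    if signal_log2_mean <= background_log2_mean:
        raise ValidationError(
            "signal_log2_mean must exceed background_log2_mean"
        )

    rng = np.random.default_rng(seed)
    n = layout.n_pairs
    probe_ids = np.asarray(layout.probe_ids)
    u = rng.uniform(size=n)  # shared stream: one draw per probe pair
    affinity = np.exp2(rng.normal(0.0, affinity_log2_sd, n))

    cols = {}
    probe_rows = []
    for g in genotypes:
        binds = u < bind_prob[g]
        signal = affinity * np.exp2(rng.normal(signal_log2_mean, signal_log2_sd, n))
        background = np.exp2(rng.normal(background_log2_mean, background_log2_sd, n))
        cols[f"gdna_{g}"] = np.where(binds, signal, background)
        probe_rows.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "genotype": g,
                    "affinity": affinity,
                    "binds": binds,
                }
            )
        )
    probes = pd.concat(probe_rows, ignore_index=True)
    if truth is not None:
        truth.probes = probes
        truth.params.update(
            {
                "bind_prob": {g: bind_prob[g] for g in genotypes},
                "signal_log2_mean": signal_log2_mean,
                "signal_log2_sd": signal_log2_sd,
                "background_log2_mean": background_log2_mean,
                "background_log2_sd": background_log2_sd,
                "affinity_log2_sd": affinity_log2_sd,
                "gdna_seed": seed,
            }
        )
    values = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    return ProbeIntensityMatrix(values)


# ---------------------------------------------------------------------------
# RNA hybridisations
# ---------------------------------------------------------------------------


def simulate_rna(
    layout: ChipLayout,
    truth: SimulationTruth,
    sheet: SampleSheet,
    noise_sd: float = 0.25,
    module_cofluct_sd: float = 1.0,
    background_log2_mean: float | None = None,
    background_log2_sd: float | None = None,
    seed: int = 0,
) -> ProbeIntensityMatrix:
    """RNA probe intensities for every non-excluded sample in ``sheet``.

    For a binding probe j of set g in sample s::

        intensity = affinity_j * 2**(baseline_g + effect + latent) * exp(eps)

    with ``eps ~ Normal(0, noise_sd * ln 2)`` (so the log2-scale noise SD is
    ``noise_sd``).  ``effect`` is the planted log2 fold change under
    water-limited treatment; responsive sets have zero effect at recovery
    while perturbed sets retain it.  ``latent`` is the module co-fluctuation:
    one Normal(0, module_cofluct_sd) draw per (module, sample) shared by all
    sets of the module — coordinated ~2-fold swings by default, the scale at
    which rank correlation over the study's ten samples per genotype can
    resolve co-regulation.  Non-binding probes draw lognormal background.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if background_log2_mean is None:
        background_log2_mean = truth.params.get("background_log2_mean", 6.0)
    if background_log2_sd is None:
        background_log2_sd = truth.params.get("background_log2_sd", 1.0)

    active = sheet.active()
    unknown = set(active["genotype"]) - set(truth.genotypes)
    if unknown:
        raise ValidationError(
            f"sample sheet genotypes {sorted(unknown)} absent from truth "
            f"{list(truth.genotypes)}"
        )
    if truth.probes is None:
        # ideal array: every probe binds with unit affinity
        truth.probes = pd.concat(
            [
                pd.DataFrame(
                    {
                        "probe_id": np.asarray(layout.probe_ids),
                        "genotype": g,
                        "affinity": 1.0,
                        "binds": True,
                    }
                )
                for g in truth.genotypes
            ],
            ignore_index=True,
        )

    rng = np.random.default_rng(seed)
    probe_ids = np.asarray(layout.probe_ids)
    set_of_probe = np.asarray(layout.table["probe_set_id"])
    set_index = pd.Index(truth.sets.index)
    probe_setpos = set_index.get_indexer(set_of_probe)
    baseline = truth.sets["baseline_log2"].to_numpy()
    module_of_set = truth.sets["module_id"].to_numpy()
    n_modules = int(module_of_set.max()) + 1 if (module_of_set >= 0).any() else 0

    # per-genotype planted effects, as dense per-set vectors
    eff_stress = {}
    eff_recovery = {}
    for g in truth.genotypes:
        stress = np.zeros(len(set_index))
        recov = np.zeros(len(set_index))
        dg = truth.de_frame(g)
        pos = set_index.get_indexer(dg.index)
        stress[pos] = dg["log2fc"].to_numpy()
        keep = dg["response_class"].to_numpy() == "perturbed"
        recov[pos[keep]] = dg["log2fc"].to_numpy()[keep]
        eff_stress[g] = stress
        eff_recovery[g] = recov

    probes_by_g = {
        g: grp.set_index("probe_id").loc[probe_ids]
        for g, grp in truth.probes.groupby("genotype")
    }

    cols = {}
    ln2 = math.log(2.0)
    for _, row in active.iterrows():
        g, treatment, sid = row["genotype"], row["treatment"], row["sample_id"]
        if treatment == "water_limited":
            effect = eff_stress[g]
        elif treatment == "recovery":
            effect = eff_recovery[g]
        else:
            effect = np.zeros(len(set_index))
        latent_per_set = np.zeros(len(set_index))
        if n_modules and module_cofluct_sd > 0:
            latent = rng.normal(0.0, module_cofluct_sd, n_modules)
            in_mod = module_of_set >= 0
            latent_per_set[in_mod] = latent[module_of_set[in_mod]]
        log2_expr = (baseline + effect + latent_per_set)[probe_setpos]

        pg = probes_by_g[g]
        affinity = pg["affinity"].to_numpy()
        binds = pg["binds"].to_numpy()
        eps = rng.normal(0.0, noise_sd * ln2, len(probe_ids))
        signal = affinity * np.exp2(log2_expr) * np.exp(eps)
        background = np.exp2(
            rng.normal(background_log2_mean, background_log2_sd, len(probe_ids))
        )
        cols[sid] = np.where(binds, signal, background)

    values = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    return ProbeIntensityMatrix(values)
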