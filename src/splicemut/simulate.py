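"""Synthetic bone-marrow cohort simulator.

Generates seeded cohorts with the statistical structure the downstream
analyses assume: donors carrying (or not) a splice-factor driver mutation,
mutant clones of configurable size within mutant donors, sparse
junction-level read coverage of cryptic-splicing events, negative-binomial
gene expression with genotype-dependent fold changes, condition-dependent
cell-type composition, and per-cell latent modulation of niche signature
genes in stromal cells (coupled or anti-coupled between two programmes,
emulating the inflammation / HSPC-support contrast between CHIP-like and
MDS-like marrows).

Every random draw flows from a single root seed through named substreams,
so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


CONDITIONS = ("Control", "CHIP", "MDS")

_DEFAULT_CELL_TYPES = ("HSC", "EryPr", "MkP", "Lymphoid", "Stromal")

# Condition-dependent type proportions: MDS marrows are erythroid-skewed,
# CHIP sits between Control and MDS; stromal fraction held constant so the
# signature analyses see comparable stromal cell numbers per condition.
_DEFAULT_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "Control": (0.25, 0.20, 0.10, 0.25, 0.20),
    "CHIP": (0.22, 0.24, 0.10, 0.24, 0.20),
    "MDS": (0.15, 0.35, 0.10, 0.20, 0.20),
}


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    The defaults mirror the analyzed cohort shape: 3 donors without the
    splice-factor mutation (condition Control) and 4 mutant donors
    (condition MDS), 400 cells per donor, 50 mis-splicing events.

    Parameters
    ----------
    psi0, psi1
        Cryptic-usage probability at an event for wild-type and mutant
        cells respectively (``0 <= psi0 < psi1 <= 1``).
    clone_fraction_per_mut_donor
        Probability that a cell of a mutant donor belongs to the mutant
        clone; wild-type donors have clone fraction 0 by construction.
    event_coverage_rate
        Mean total reads per event per cell (Poisson rate); controls the
        sparsity the >=2-covered-events filter acts on.
    nb_dispersion
        NB2 dispersion alpha of gene counts (variance mu + alpha*mu^2).
    de_log2fc
        True log2 fold change applied to the first ``n_de_genes`` genes in
        mutant cells.
    signature_effect
        Scale (in log2 units) of the per-cell latent modulation of the two
        niche signature gene sets in ``signature_cell_types``.
    signature_coupling
        Per-condition correlation (-1, 0 or +1 typically) between the
        latent factors driving the inflammation-like and support-like
        signature sets; negative reproduces a CHIP-like anti-coupling,
        positive an MDS-like coupling.
    psi_jitter_concentration
        Optional Beta concentration; when set, per-event psi values are
        jittered around psi0/psi1 (``Beta(c*psi, c*(1-psi))``). Off by
        default.
    """

    n_wt_donors: int = 3
    n_mut_donors: int = 4
    cells_per_donor: int = 400
    n_events: int = 50
    clone_fraction_per_mut_donor: float = 0.6
    psi0: float = 0.02
    psi1: float = 0.35
    event_coverage_rate: float = 0.6
    n_genes: int = 2000
    n_de_genes: int = 100
    de_log2fc: float = 1.0
    nb_dispersion: float = 0.1
    cell_types: tuple[str, ...] = _DEFAULT_CELL_TYPES
    cell_type_proportions_by_condition: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_PROPORTIONS.items()}
    )
    n_signature_genes: int = 30
    signature_effect: float = 0.5
    signature_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"Control": 0.0, "CHIP": -0.9, "MDS": 0.9}
    )
    signature_cell_types: tuple[str, ...] = ("Stromal",)
    library_size_sigma: float = 0.3
    psi_jitter_concentration: float | None = None
    wt_conditions: tuple[str, ...] | None = None
    mut_conditions: tuple[str, ...] | None = None
    seed: int = 0

    @classmethod
    def full_cohort(cls, **overrides) -> "SimConfig":
        """Cohort with all three conditions: 3 Control, 3 CHIP, 4 MDS donors.

        CHIP donors carry non-splice-factor drivers, hence are wild type for
        the splice classifier but form their own condition for composition
        and niche analyses.
        """
        cfg = dict(
            n_wt_donors=6,
            n_mut_donors=4,
            wt_conditions=("Control",) * 3 + ("CHIP",) * 3,
            mut_conditions=("MDS",) * 4,
        )
        cfg.update(overrides)
        return cls(**cfg)

    def validate(self) -> None:
        for name in ("n_wt_donors", "n_mut_donors", "cells_per_donor",
                     "n_events", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise SimConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not (0 <= self.n_de_genes <= self.n_genes):
            raise SimConfigError("n_de_genes must lie in [0, n_genes]")
        for name in ("clone_fraction_per_mut_donor", "psi0", "psi1"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be a finite probability in [0,1], got {v!r}")
        if not self.psi0 <= self.psi1:
            raise SimConfigError("psi0 must be <= psi1")
        if not (np.isfinite(self.event_coverage_rate) and self.event_coverage_rate > 0):
            raise SimConfigError("event_coverage_rate must be finite and > 0")
        if not (np.isfinite(self.nb_dispersion) and self.nb_dispersion > 0):
            raise SimConfigError("nb_dispersion must be finite and > 0")
        if not np.isfinite(self.de_log2fc):
            raise SimConfigError("de_log2fc must be finite")
        conds = set(self._donor_conditions())
        for cond in conds:
            if cond not in self.cell_type_proportions_by_condition:
                raise SimConfigError(f"no cell-type proportions for condition {cond!r}")
        for cond, props in self.cell_type_proportions_by_condition.items():
            props = np.asarray(props, dtype=float)
            if props.shape != (len(self.cell_types),):
                raise SimConfigError(
                    f"proportion vector for {cond!r} has length {props.size}, "
                    f"expected {len(self.cell_types)}"
                )
            if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
                raise SimConfigError(f"proportions for {cond!r} must be a simplex")
        if 2 * self.n_signature_genes > self.n_genes - self.n_de_genes:
            raise SimConfigError("not enough non-DE genes to host two signatures")

    def _donor_conditions(self) -> list[str]:
        wt = self.wt_conditions or ("Control",) * self.n_wt_donors
        mut = self.mut_conditions or ("MDS",) * self.n_mut_donors
        if len(wt) != self.n_wt_donors or len(mut) != self.n_mut_donors:
            raise SimConfigError("condition lists must match donor counts")
        return list(wt) + list(mut)

    def to_json(self) -> str:
        d = asdict(self)
        d["cell_type_proportions_by_condition"] = {
            k: list(map(float, v))
            for k, v in self.cell_type_proportions_by_condition.items()
        }
        return json.dumps(d, indent=2, default=list)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    cell_genotype: pd.Series          # index cell_id, values {"MUT","WT"}
    event_psi: pd.DataFrame           # index event_id, columns psi0/psi1
    gene_log2fc: pd.Series            # index gene, true log2FC (0 if not DE)
    cell_type_proportions: dict[str, np.ndarray]
    signature_genes: dict[str, list[str]]
    donor_table: pd.DataFrame         # donor, sf3b1_status, condition, clone_fraction


@dataclass
class SimResult:
    junctions: ad.AnnData             # cells x events; layers canonical/cryptic
    expression: ad.AnnData            # cells x genes raw counts + obs metadata
    donors: pd.DataFrame
    truth: SimTruth


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_cohort(config: SimConfig) -> SimResult:
    """Draw a full synthetic cohort from ``config``.

    Per cell c of donor d the true genotype is Bernoulli(clone fraction of
    d); per event the total junction reads are Poisson(coverage rate) and
    cryptic reads Binomial(total, psi1 if MUT else psi0); gene counts are
    NB2 with mutant means scaled by ``2**log2fc`` for DE genes; cell types
    are multinomial draws from the donor condition's proportion vector.
    """
    config.validate()
    rngs = _substreams(config.seed, [
        "genotype", "coverage", "cryptic", "celltype", "expression",
        "psi_jitter", "signature",
    ])

    donor_conditions = config._donor_conditions()
    n_donors = config.n_wt_donors + config.n_mut_donors
    donor_ids = [f"D{i + 1:02d}" for i in range(n_donors)]
    status = ["WT"] * config.n_wt_donors + ["MUT"] * config.n_mut_donors
    clone_fracs = [0.0] * config.n_wt_donors + [
        config.clone_fraction_per_mut_donor
    ] * config.n_mut_donors
    donors = pd.DataFrame({
        "donor": donor_ids,
        "sf3b1_status": status,
        "condition": donor_conditions,
        "clone_fraction": clone_fracs,
    }).set_index("donor", drop=False)

    n_cells = n_donors * config.cells_per_donor
    cell_donor = np.repeat(donor_ids, config.cells_per_donor)
    cell_ids = np.array([
        f"{d}_c{j:04d}"
        for d in donor_ids
        for j in range(config.cells_per_donor)
    ])
    cell_condition = np.repeat(donor_conditions, config.cells_per_donor)

    # genotypes: Bernoulli(clone fraction), zero for WT donors
    frac_per_cell = np.repeat(clone_fracs, config.cells_per_donor)
    is_mut = rngs["genotype"].random(n_cells) < frac_per_cell

    # cell types from condition proportions
    type_idx = np.empty(n_cells, dtype=int)
    n_types = len(config.cell_types)
    for cond in set(donor_conditions):
        m = cell_condition == cond
        p = np.asarray(config.cell_type_proportions_by_condition[cond], dtype=float)
        type_idx[m] = rngs["celltype"].choice(n_types, size=m.sum(), p=p / p.sum())
    cell_type = np.asarray(config.cell_types)[type_idx]

    # junction counts
    event_ids = [f"ev{e:03d}" for e in range(config.n_events)]
    if config.psi_jitter_concentration:
        c = float(config.psi_jitter_concentration)
        psi0_e = rngs["psi_jitter"].beta(
            np.maximum(c * config.psi0, 1e-9),
            np.maximum(c * (1 - config.psi0), 1e-9), size=config.n_events)
        psi1_e = rngs["psi_jitter"].beta(
            np.maximum(c * config.psi1, 1e-9),
            np.maximum(c * (1 - config.psi1), 1e-9), size=config.n_events)
    else:
        psi0_e = np.full(config.n_events, config.psi0)
        psi1_e = np.full(config.n_events, config.psi1)

    total = rngs["coverage"].poisson(
        config.event_coverage_rate, size=(n_cells, config.n_events))
    psi_cell = np.where(is_mut[:, None], psi1_e[None, :], psi0_e[None, :])
    cryptic = rngs["cryptic"].binomial(total, psi_cell)
    canonical = total - cryptic

    event_table = pd.DataFrame({
        "event_id": event_ids,
        "gene": [f"SFGENE{e:03d}" for e in range(config.n_events)],
        "event_class": ["A3SS" if e % 2 == 0 else "SE" for e in range(config.n_events)],
        "canonical_junction": [f"jx_can_{e:03d}" for e in range(config.n_events)],
        "cryptic_junction": [f"jx_cry_{e:03d}" for e in range(config.n_events)],
    }).set_index("event_id", drop=False)

    obs = pd.DataFrame({
        "donor": cell_donor,
        "condition": pd.Categorical(cell_condition),
        "cell_type": pd.Categorical(cell_type, categories=list(config.cell_types)),
        "true_genotype": np.where(is_mut, "MUT", "WT"),
    }, index=pd.Index(cell_ids, name="cell_id"))

    junctions = ad.AnnData(
        X=sparse.csr_matrix(total.astype(np.int64)),
        obs=obs.copy(),
        var=event_table,
        layers={
            "canonical": sparse.csr_matrix(canonical.astype(np.int64)),
            "cryptic": sparse.csr_matrix(cryptic.astype(np.int64)),
        },
    )

    # gene expression: NB2 counts, lognormal base means, per-cell size factor
    gene_ids = np.array([f"g{j:04d}" for j in range(config.n_genes)])
    rng_e = rngs["expression"]
    base_mean = rng_e.lognormal(mean=0.7, sigma=1.0, size=config.n_genes)
    log2fc = np.zeros(config.n_genes)
    log2fc[: config.n_de_genes] = config.de_log2fc

    sig_start = config.n_de_genes
    sig_genes = {
        "inflammation": list(gene_ids[sig_start: sig_start + config.n_signature_genes]),
        "hspc_support": list(gene_ids[
            sig_start + config.n_signature_genes:
            sig_start + 2 * config.n_signature_genes]),
    }
    infl_idx = np.arange(sig_start, sig_start + config.n_signature_genes)
    supp_idx = infl_idx + config.n_signature_genes

    cell_sf = rng_e.lognormal(mean=0.0, sigma=config.library_size_sigma, size=n_cells)
    mu = np.outer(cell_sf, base_mean)
    mu[is_mut] *= 2.0 ** log2fc[None, :]

    # latent coupled/anti-coupled modulation of the two signature programmes
    # in the designated (stromal) cell types
    rng_s = rngs["signature"]
    in_sig_type = np.isin(cell_type, config.signature_cell_types)
    if config.signature_effect != 0 and in_sig_type.any():
        z1 = rng_s.standard_normal(n_cells)
        z2 = rng_s.standard_normal(n_cells)
        rho = np.array([
            float(config.signature_coupling.get(c, 0.0)) for c in cell_condition
        ])
        rho = np.clip(rho, -1.0, 1.0)
        z_sup = rho * z1 + np.sqrt(1.0 - rho ** 2) * z2
        scale = config.signature_effect
        mod = np.where(in_sig_type, 1.0, 0.0)
        mu[:, infl_idx] *= 2.0 ** (scale * z1 * mod)[:, None]
        mu[:, supp_idx] *= 2.0 ** (scale * z_sup * mod)[:, None]

    # NB2 via Gamma-Poisson mixture: shape 1/alpha, mean mu
    alpha = config.nb_dispersion
    lam = rng_e.gamma(shape=1.0 / alpha, scale=alpha * mu)
    counts = rng_e.poisson(lam)

    expression = ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=obs.copy(),
        var=pd.DataFrame(
            {"gene": gene_ids, "true_log2fc": log2fc},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
    )

    truth = SimTruth(
        cell_genotype=pd.Series(np.where(is_mut, "MUT", "WT"), index=cell_ids,
                                name="true_genotype"),
        event_psi=pd.DataFrame({"psi0": psi0_e, "psi1": psi1_e},
                               index=pd.Index(event_ids, name="event_id")),
        gene_log2fc=pd.Series(log2fc, index=gene_ids, name="true_log2fc"),
        cell_type_proportions={
            c: np.asarray(config.cell_type_proportions_by_condition[c], dtype=float)
            for c in set(donor_conditions)
        },
        signature_genes=sig_genes,
        donor_table=donors,
    )
    return SimResult(junctions=junctions, expression=expression,
                     donors=donors, truth=truth)


def write_cohort(result: SimResult, outdir: str | Path, config: SimConfig | None = None) -> None:
    """Write a simulated cohort as MatrixMarket matrices + TSV sidecars."""
    from . import io as smio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    smio.write_counts(result.expression, outdir / "expression")
    smio.write_counts(result.junctions, outdir / "junctions",
                      layers=("canonical", "cryptic"))
    result.donors.to_csv(outdir / "donors.tsv", sep="\t", index=False)
    truth = result.truth
    truth.cell_genotype.rename_axis("cell_id").to_frame().to_csv(
        outdir / "truth_cell_genotype.tsv", sep="\t")
    truth.event_psi.to_csv(outdir / "truth_event_psi.tsv", sep="\t")
    truth.gene_log2fc.rename_axis("gene").to_frame().to_csv(
        outdir / "truth_gene_log2fc.tsv", sep="\t")
    pd.DataFrame(
        [(s, g) for s, gl in truth.signature_genes.items() for g in gl],
        columns=["signature", "gene"],
    ).to_csv(outdir / "truth_signatures.tsv", sep="\t", index=False)
    if config is not None:
        (outdir / "config.json").write_text(config.to_json())
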