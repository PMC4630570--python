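"""Seeded synthetic data with known statistical structure.

This module emulates the data layer of a methyl-jasmonate (MeJA) elicitation
study on hairy-root cultures: transcript time courses for a transcription
factor (TF) panel plus phenylpropanoid/lignan pathway genes, metabolite
profiles coupled to the transcripts through a latent induction factor, a
protein set with planted AP2/ERF family architectures, and qPCR Ct tables.
Every generator is a pure function of its spec (including the seed), so the
whole downstream pipeline is testable without any external download, and the
planted quantities (fold changes, regulation classes, pairwise correlations,
the first canonical correlation) are known by construction.

Sample columns are named ``t<h>h_r<rep>`` (e.g. ``t6h_r2``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSpec",
    "InductionConfig",
    "CouplingSpec",
    "CouplingTruth",
    "CoupledMetabolites",
    "ProteinSetSpec",
    "gen_timecourse_expression",
    "gen_coupled_metabolites",
    "gen_protein_set",
    "gen_qpcr_ct",
    "default_induction_config",
    "default_coupling_spec",
    "sample_columns",
    "parse_sample_column",
]

RegulationClass = Literal["up", "down", "mixed", "undetectable"]
REGULATION_CLASSES = ("up", "down", "mixed", "undetectable")

# Peak induction folds reported for the eight phenylpropanoid/lignan pathway
# genes after MeJA elicitation; 4CL and PLR peak at 12 h, the rest at 6 h.
PATHWAY_GENE_FOLDS: dict[str, tuple[float, float]] = {
    "IiPAL": (2.7, 6.0),
    "IiC4H": (3.9, 6.0),
    "Ii4CL": (3.0, 12.0),
    "IiC3H": (11.5, 6.0),
    "IiCCR": (6.0, 6.0),
    "IiCAD": (4.9, 6.0),
    "IiDIR": (6.1, 6.0),
    "IiPLR": (2.7, 12.0),
}

LIGNAN_METABOLITES = (
    "coniferin",
    "lariciresinol",
    "secoisolariciresinol",
    "pinoresinol",
)

DEFAULT_TIMEPOINTS = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0)


def sample_columns(timepoints_h: Sequence[float], n_replicates: int) -> list[str]:
    """Column labels ``t<h>h_r<rep>`` in timepoint-major order."""
    cols = []
    for t in timepoints_h:
        th = int(t) if float(t).is_integer() else t
        for r in range(1, n_replicates + 1):
            cols.append(f"t{th}h_r{r}")
    return cols


def parse_sample_column(name: str) -> tuple[float, int]:
    """Inverse of :func:`sample_columns` for one label."""
    if not name.startswith("t") or "h_r" not in name:
        raise ValueError(f"malformed sample column name: {name!r}")
    t_part, r_part = name[1:].split("h_r")
    return float(t_part), int(r_part)


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: identity, regulation class and induction kinetics.

    ``peak_fold`` is the noise-free abundance ratio versus 0 h at
    ``peak_time_h`` (for class ``down`` it is < 1, a trough).
    """

    gene_id: str
    regulation_class: RegulationClass
    peak_fold: float
    peak_time_h: float
    role: Literal["TF", "pathway_gene"] = "TF"


@dataclass(frozen=True)
class InductionConfig:
    timepoints_h: tuple[float, ...]
    n_replicates: int
    gene_specs: tuple[GeneSpec, ...]
    noise_cv: float = 0.0
    baseline_abundance: float = 100.0
    seed: int = 0
    # fraction of the peak ln-fold still present at the final timepoint for
    # up/down classes (post-peak relaxation); mixed ignores it and decays to
    # the reciprocal fold
    relax_fraction: float = 0.3

    def __post_init__(self) -> None:
        tps = self.timepoints_h
        if len(tps) < 2 or list(tps) != sorted(set(tps)):
            raise ValueError("timepoints_h must be strictly increasing")
        if tps[0] != 0:
            raise ValueError("timepoints_h must start at 0 h (the control)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.baseline_abundance <= 0:
            raise ValueError("baseline_abundance must be positive")
        seen: set[str] = set()
        for g in self.gene_specs:
            if g.regulation_class not in REGULATION_CLASSES:
                raise ValueError(
                    f"{g.gene_id}: unknown regulation class {g.regulation_class!r}"
                )
            if g.peak_time_h not in tps:
                raise ValueError(
                    f"{g.gene_id}: peak_time_h {g.peak_time_h} is not a configured timepoint"
                )
            if g.peak_time_h <= 0:
                raise ValueError(f"{g.gene_id}: peak_time_h must be a post-treatment timepoint")
            if g.peak_fold <= 0:
                raise ValueError(f"{g.gene_id}: peak_fold must be positive")
            if g.regulation_class == "up" and g.peak_fold <= 1:
                raise ValueError(f"{g.gene_id}: class 'up' requires peak_fold > 1")
            if g.regulation_class == "down" and g.peak_fold >= 1:
                raise ValueError(f"{g.gene_id}: class 'down' requires peak_fold < 1")
            if g.regulation_class == "mixed":
                if g.peak_fold <= 1:
                    raise ValueError(f"{g.gene_id}: class 'mixed' requires peak_fold > 1")
                if g.peak_time_h >= tps[-1]:
                    raise ValueError(
                        f"{g.gene_id}: class 'mixed' needs peak before the final timepoint"
                    )
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)


def _ln_fold_profile(spec: GeneSpec, timepoints: Sequence[float], relax: float) -> np.ndarray:
    """Noise-free ln(fold vs 0 h) at each configured timepoint.

    Piecewise log-linear: 0 at 0 h, ln(peak_fold) at the peak, then a linear
    relaxation on the ln scale.  ``mixed`` overshoots through zero down to
    -ln(peak_fold) at the final timepoint so the gene is up early and down
    late; ``up``/``down`` stay strictly on their side of zero.
    """
    tps = np.asarray(timepoints, dtype=float)
    lnp = math.log(spec.peak_fold)
    t_peak, t_end = spec.peak_time_h, tps[-1]
    if spec.regulation_class == "mixed":
        end_ln = -lnp
    elif t_peak == t_end:
        end_ln = lnp
    else:
        end_ln = relax * lnp
    out = np.empty_like(tps)
    rising = tps <= t_peak
    out[rising] = lnp * (tps[rising] / t_peak) if t_peak > 0 else lnp
    falling = ~rising
    if t_end > t_peak:
        out[falling] = lnp + (end_ln - lnp) * (tps[falling] - t_peak) / (t_end - t_peak)
    return out


def gen_timecourse_expression(config: InductionConfig) -> pd.DataFrame:
    """Simulate an abundance matrix (genes x ``t<h>h_r<rep>`` samples).

    Each gene follows its unimodal piecewise log-linear profile through
    (0 h, baseline) and (peak_time, baseline x peak_fold), perturbed by
    multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (mean-one, so expectations stay on the planted curve).
    Genes of class ``undetectable`` are masked (NaN) at a seeded, non-empty
    subset of post-treatment timepoints across all replicates.
    """
    rng = np.random.default_rng(config.seed)
    tps = np.asarray(config.timepoints_h, dtype=float)
    n_t, n_r = len(tps), config.n_replicates
    cols = sample_columns(tps, n_r)
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log1p(config.noise_cv**2))
    else:
        sigma = 0.0

    rows = np.empty((len(config.gene_specs), n_t * n_r))
    for i, spec in enumerate(config.gene_specs):
        ln_profile = _ln_fold_profile(spec, tps, config.relax_fraction)
        values = config.baseline_abundance * np.exp(np.repeat(ln_profile, n_r))
        if sigma > 0:
            noise = rng.normal(-0.5 * sigma**2, sigma, size=values.shape)
            values = values * np.exp(noise)
        if spec.regulation_class == "undetectable":
            n_post = n_t - 1
            n_mask = 1 + int(rng.integers(0, n_post))
            masked = rng.choice(np.arange(1, n_t), size=n_mask, replace=False)
            for t_idx in masked:
                values[t_idx * n_r : (t_idx + 1) * n_r] = np.nan
        rows[i] = values

    return pd.DataFrame(rows, index=[g.gene_id for g in config.gene_specs], columns=cols)


def default_induction_config(
    n_replicates: int = 3,
    noise_cv: float = 0.2,
    seed: int = 0,
    n_tfs: int = 112,
) -> InductionConfig:
    """The study's default conditions.

    Eight pathway genes at their reported peak folds, and a TF panel whose
    regulation classes split 13 up / 30 down / 42 mixed / 27 undetectable
    (scaled proportionally if ``n_tfs`` != 112).  Up-regulated TF peak folds
    span 2-8.2 and down-regulated 1/2-1/6.5, bracketing the strongest
    reported TF responses.
    """
    genes: list[GeneSpec] = [
        GeneSpec(gid, "up", fold, peak, role="pathway_gene")
        for gid, (fold, peak) in PATHWAY_GENE_FOLDS.items()
    ]
    counts = {"up": 13, "down": 30, "mixed": 42, "undetectable": 27}
    if n_tfs != 112:
        scaled = {k: max(1, round(v * n_tfs / 112)) for k, v in counts.items()}
        while sum(scaled.values()) > n_tfs:
            scaled["mixed"] -= 1
        scaled["mixed"] += n_tfs - sum(scaled.values())
        counts = scaled
    idx = 0
    for cls, n in counts.items():
        for j in range(n):
            idx += 1
            frac = j / max(n - 1, 1)
            if cls == "up":
                fold = 2.0 + frac * 6.2
            elif cls == "down":
                fold = 1.0 / (2.0 + frac * 4.5)
            else:  # mixed / undetectable: moderate induction amplitudes
                fold = 2.0 + frac * 2.0
            peak = 6.0 if (cls != "mixed" or idx % 2) else 12.0
            genes.append(GeneSpec(f"Ii{idx:03d}", cls, fold, peak, role="TF"))
    return InductionConfig(
        timepoints_h=DEFAULT_TIMEPOINTS,
        n_replicates=n_replicates,
        gene_specs=tuple(genes),
        noise_cv=noise_cv,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# metabolites coupled through a latent induction factor


@dataclass(frozen=True)
class CouplingSpec:
    """Single-factor coupling between transcripts and metabolites.

    The latent induction factor z is a unit-variance linear combination
    (weights ``latent_loadings_x``) of the coupled genes' z-scored ln
    abundances; metabolite k is ``latent_loadings_y[k] * z`` plus independent
    N(0, residual_sd^2) noise.  Because z lies exactly in the span of the
    gene block, the population first canonical correlation between the gene
    and metabolite blocks is ||b|| / sqrt(||b||^2 + residual_sd^2) in closed
    form; setting ``target_rho1`` rescales b to hit a requested value.
    """

    metabolite_ids: tuple[str, ...]
    coupled_gene_ids: tuple[str, ...]
    latent_loadings_x: tuple[float, ...] | None = None
    latent_loadings_y: tuple[float, ...] | None = None
    residual_sd: float = 1.0
    target_rho1: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.latent_loadings_x is not None and len(self.latent_loadings_x) != len(
            self.coupled_gene_ids
        ):
            raise ValueError("latent_loadings_x length must match coupled_gene_ids")
        if self.latent_loadings_y is not None and len(self.latent_loadings_y) != len(
            self.metabolite_ids
        ):
            raise ValueError("latent_loadings_y length must match metabolite_ids")
        if self.target_rho1 is not None and not (0 < self.target_rho1 < 1):
            raise ValueError("target_rho1 must lie in (0, 1)")
        if self.target_rho1 is not None and self.residual_sd == 0:
            raise ValueError("target_rho1 requires residual_sd > 0")


@dataclass(frozen=True)
class CouplingTruth:
    """Ground truth attached to a generated metabolite matrix.

    ``rho1`` is the population first canonical correlation; ``gene_metabolite_r``
    holds the population Pearson correlation between each coupled gene's ln
    abundance and each metabolite (rows = coupled genes, cols = metabolites).
    """

    rho1: float
    y_loadings: tuple[float, ...]
    residual_sd: float
    gene_metabolite_r: pd.DataFrame
    latent_corr_x: pd.Series  # corr of each coupled gene's ln abundance with z


@dataclass(frozen=True)
class CoupledMetabolites:
    values: pd.DataFrame  # metabolites x samples
    truth: CouplingTruth


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("coupled gene with constant profile cannot carry a latent factor")
    return (M - mu) / sd


def gen_coupled_metabolites(expr: pd.DataFrame, coupling: CouplingSpec) -> CoupledMetabolites:
    """Generate metabolite profiles coupled to transcripts via one latent factor.

    ``expr`` is an abundance matrix from :func:`gen_timecourse_expression`
    (positive, no NaN among the coupled genes).  Metabolite values are on an
    arbitrary standardized concentration scale; the attached
    :class:`CouplingTruth` records the planted population correlations.
    """
    missing = [g for g in coupling.coupled_gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"coupled genes absent from expression matrix: {missing}")
    sub = expr.loc[list(coupling.coupled_gene_ids)].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise ValueError("coupled genes must have no missing values")
    if (sub <= 0).any():
        raise ValueError("abundances must be positive for log transform")
    Z = _zscore_rows(np.log(sub))  # genes x samples, each row ~ (0, 1)

    p = len(coupling.coupled_gene_ids)
    w = (
        np.full(p, 1.0 / p)
        if coupling.latent_loadings_x is None
        else np.asarray(coupling.latent_loadings_x, dtype=float)
    )
    z_raw = w @ Z
    z_sd = z_raw.std(ddof=1)
    if z_sd == 0:
        raise ValueError("latent factor degenerate (zero variance)")
    z = (z_raw - z_raw.mean()) / z_sd

    q = len(coupling.metabolite_ids)
    b = (
        np.full(q, 1.0)
        if coupling.latent_loadings_y is None
        else np.asarray(coupling.latent_loadings_y, dtype=float)
    )
    s = coupling.residual_sd
    if coupling.target_rho1 is not None:
        norm_b = np.linalg.norm(b)
        if norm_b == 0:
            raise ValueError("target_rho1 requires a non-zero latent_loadings_y")
        rho = coupling.target_rho1
        b = b * (rho * s / (norm_b * math.sqrt(1 - rho**2)))

    rng = np.random.default_rng(coupling.seed)
    resid = rng.normal(0.0, 1.0, size=(q, Z.shape[1])) if s > 0 else np.zeros((q, Z.shape[1]))
    Y = b[:, None] * z[None, :] + s * resid

    norm_b = float(np.linalg.norm(b))
    rho1 = norm_b / math.sqrt(norm_b**2 + s**2) if (norm_b or s) else 0.0
    # corr(x_j, z): z is a fixed combination of the realized z-scored genes
    a = Z @ z / (Z.shape[1] - 1)
    met_sd = np.sqrt(b**2 + s**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.outer(a, np.where(met_sd > 0, b / met_sd, 0.0))
    truth = CouplingTruth(
        rho1=rho1,
        y_loadings=tuple(float(v) for v in b),
        residual_sd=s,
        gene_metabolite_r=pd.DataFrame(
            r, index=list(coupling.coupled_gene_ids), columns=list(coupling.metabolite_ids)
        ),
        latent_corr_x=pd.Series(a, index=list(coupling.coupled_gene_ids)),
    )
    values = pd.DataFrame(Y, index=list(coupling.metabolite_ids), columns=expr.columns)
    return CoupledMetabolites(values=values, truth=truth)


def default_coupling_spec(target_rho1: float = 0.968, seed: int = 0) -> CouplingSpec:
    """Four lignan metabolites coupled to the eight pathway genes."""
    return CouplingSpec(
        metabolite_ids=LIGNAN_METABOLITES,
        coupled_gene_ids=tuple(PATHWAY_GENE_FOLDS),
        latent_loadings_y=(0.4, 1.0, 0.6, 0.8),
        residual_sd=1.0,
        target_rho1=target_rho1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# protein set with planted AP2/ERF architectures

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FAMILIES = ("ERF", "DREB", "AP2", "RAV", "Soloist")

# signature residues at AP2-domain positions 14 and 19
_SIGNATURE = {"DREB": ("A", "D"), "ERF": ("V", "E")}


@dataclass(frozen=True)
class ProteinSetSpec:
    n_per_family: dict[str, int] = field(
        default_factory=lambda: {"ERF": 4, "DREB": 4, "AP2": 3, "RAV": 2, "Soloist": 1}
    )
    n_decoys: int = 0
    duplicate_pairs: tuple[tuple[str, str, float], ...] = ()
    domain_length: int = 60
    linker_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for fam, n in self.n_per_family.items():
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}")
            if n < 0:
                raise ValueError("family counts must be non-negative")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")
        for _, _, ident in self.duplicate_pairs:
            if not 0 <= ident <= 1:
                raise ValueError("target_identity must lie in [0, 1]")
        if self.domain_length < 25:
            raise ValueError("domain_length must allow signature positions (>= 25)")


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _ap2_domain(rng: np.random.Generator, length: int, family: str | None) -> str:
    core = list(_random_peptide(rng, length))
    if family in _SIGNATURE:
        core[13], core[18] = _SIGNATURE[family]
    else:
        # neutral residues distinct from both signatures
        core[13], core[18] = "G", "G"
    return "".join(core)


def gen_protein_set(
    spec: ProteinSetSpec,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate (sequences, domain table, homology-hit table).

    Sequences carry the domain architecture of their planted family (two AP2
    domains for AP2, AP2+B3 for RAV, one AP2 with subfamily signature
    residues for ERF/DREB, one flagged AP2 for Soloist).  Decoys have no AP2
    domain and each fails at least one homology filter (the failing filter
    rotates).  ``duplicate_pairs`` (id1, id2, identity) plants near-identical
    paralogs: id2 is id1 mutated at round((1-identity)*L) positions.

    Returns sequences as an ordered mapping id -> sequence, a domain table
    (protein_id, domain_type, start, end, residue14, residue19, soloist), and
    a BLAST-tabular-style hit table (query_id, subject_id, evalue, bitscore,
    aln_length).
    """
    rng = np.random.default_rng(spec.seed)
    seqs: dict[str, str] = {}
    dom_rows: list[dict] = []
    hit_rows: list[dict] = []
    families: dict[str, str] = {}

    def add_domain(pid: str, dtype: str, start: int, seq: str) -> None:
        dom_rows.append(
            {
                "protein_id": pid,
                "domain_type": dtype,
                "start": start,
                "end": start + len(seq) - 1,
                "residue14": seq[13] if dtype == "AP2" else "",
                "residue19": seq[18] if dtype == "AP2" else "",
                "soloist": families[pid] == "Soloist",
            }
        )

    counter = 0
    for fam in FAMILIES:
        for _ in range(spec.n_per_family.get(fam, 0)):
            counter += 1
            pid = f"Ii{counter:03d}"
            families[pid] = fam
            nterm = _random_peptide(rng, spec.linker_length)
            parts = [nterm]
            pos = len(nterm) + 1
            if fam == "AP2":
                for _ in range(2):
                    d = _ap2_domain(rng, spec.domain_length, None)
                    add_domain(pid, "AP2", pos, d)
                    link = _random_peptide(rng, spec.linker_length)
                    parts += [d, link]
                    pos += len(d) + len(link)
            elif fam == "RAV":
                d = _ap2_domain(rng, spec.domain_length, None)
                add_domain(pid, "AP2", pos, d)
                link = _random_peptide(rng, spec.linker_length)
                parts += [d, link]
                pos += len(d) + len(link)
                b3 = _random_peptide(rng, spec.domain_length)
                add_domain(pid, "B3", pos, b3)
                parts.append(b3)
                pos += len(b3)
            else:  # ERF, DREB, Soloist: single AP2 domain
                d = _ap2_domain(rng, spec.domain_length, fam if fam in _SIGNATURE else None)
                add_domain(pid, "AP2", pos, d)
                parts.append(d)
                pos += len(d)
            parts.append(_random_peptide(rng, spec.linker_length))
            seqs[pid] = "".join(parts)
            hit_rows.append(
                {
                    "query_id": pid,
                    "subject_id": f"At{counter:03d}",
                    "evalue": 1e-30,
                    "bitscore": 200.0,
                    "aln_length": 150,
                }
            )

    fail_modes = ("evalue", "bitscore", "aln_length")
    for i in range(spec.n_decoys):
        counter += 1
        pid = f"Decoy{i + 1:03d}"
        families[pid] = "decoy"
        seqs[pid] = _random_peptide(rng, 2 * spec.linker_length + spec.domain_length)
        mode = fail_modes[i % 3]
        hit_rows.append(
            {
                "query_id": pid,
                "subject_id": f"At{counter:03d}",
                "evalue": 1e-3 if mode == "evalue" else 1e-30,
                "bitscore": 40.0 if mode == "bitscore" else 200.0,
                "aln_length": 30 if mode == "aln_length" else 150,
            }
        )

    for id1, id2, ident in spec.duplicate_pairs:
        if id1 not in seqs:
            raise KeyError(f"duplicate pair references unknown protein {id1!r}")
        src = seqs[id1]
        n_mut = round((1 - ident) * len(src))
        if n_mut > len(src):
            raise ValueError(f"identity target {ident} infeasible for length {len(src)}")
        positions = rng.choice(len(src), size=n_mut, replace=False)
        mutated = list(src)
        for p in positions:
            choices = [aa for aa in AMINO_ACIDS if aa != src[p]]
            mutated[p] = choices[int(rng.integers(len(choices)))]
        seqs[id2] = "".join(mutated)
        families[id2] = families[id1]
        # copy of id1's domain annotations at identical coordinates
        for row in [r for r in dom_rows if r["protein_id"] == id1]:
            dup = dict(row)
            dup["protein_id"] = id2
            dup["residue14"] = seqs[id2][row["start"] - 1 + 13] if row["domain_type"] == "AP2" else ""
            dup["residue19"] = seqs[id2][row["start"] - 1 + 18] if row["domain_type"] == "AP2" else ""
            dom_rows.append(dup)
        hit_rows.append(
            {
                "query_id": id2,
                "subject_id": f"At{id1}",
                "evalue": 1e-30,
                "bitscore": 200.0,
                "aln_length": 150,
            }
        )

    domains = pd.DataFrame(
        dom_rows, columns=["protein_id", "domain_type", "start", "end", "residue14", "residue19", "soloist"]
    )
    hits = pd.DataFrame(hit_rows, columns=["query_id", "subject_id", "evalue", "bitscore", "aln_length"])
    domains.attrs["planted_families"] = families
    return seqs, domains, hits


# ---------------------------------------------------------------------------
# qPCR Ct tables


def gen_qpcr_ct(
    expr: pd.DataFrame,
    efficiency: float = 2.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    reference_gene: str = "ubiquitin",
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Forward-simulate Ct values whose ddCt back-transform recovers ``expr``.

    Ct for a target gene is ``30 - log_E(abundance / baseline)`` with E the
    amplification efficiency; the reference gene (default *ubiquitin*) is
    constant across samples in noise-free mode.  0 h samples are flagged as
    the calibrator condition.  Gaussian noise of ``noise_sd`` cycles is added
    on the Ct scale when requested.
    """
    if not 1 < efficiency <= 2:
        raise ValueError("efficiency must lie in (1, 2]")
    vals = expr.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ValueError("abundances must be positive to map onto the Ct scale")
    rng = np.random.default_rng(seed)
    log_e = math.log(efficiency)
    baseline = np.nanmean(vals)
    rows = []
    for sample in expr.columns:
        t, _rep = parse_sample_column(sample)
        calibrator = t == 0
        for gene in expr.index:
            a = expr.at[gene, sample]
            if np.isnan(a):
                continue
            ct = 30.0 - math.log(a / baseline) / log_e
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "sample_id": sample,
                    "gene_id": gene,
                    "ct": ct,
                    "role": "target",
                    "calibrator": calibrator,
                }
            )
        ref_ct = reference_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append(
            {
                "sample_id": sample,
                "gene_id": reference_gene,
                "ct": ref_ct,
                "role": "reference",
                "calibrator": calibrator,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "ct", "role", "calibrator"])


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(
    outdir: str | Path,
    config: InductionConfig | None = None,
    coupling: CouplingSpec | None = None,
    protein_spec: ProteinSetSpec | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a full synthetic dataset (TSV/FASTA/JSON sidecar) to ``outdir``.

    The single ``seed`` drives named substreams for each generator unless the
    individual specs already carry seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sub = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in
           zip(("expr", "coupling", "proteins", "qpcr"), ss.spawn(4))}
    if config is None:
        config = default_induction_config(seed=sub["expr"])
    if coupling is None:
        coupling = default_coupling_spec(seed=sub["coupling"])
    if protein_spec is None:
        protein_spec = ProteinSetSpec(seed=sub["proteins"])

    expr = gen_timecourse_expression(config)
    coupled = gen_coupled_metabolites(expr, coupling)
    seqs, domains, hits = gen_protein_set(protein_spec)
    ct = gen_qpcr_ct(
        expr.loc[[g.gene_id for g in config.gene_specs if g.role == "pathway_gene"]].dropna(),
        seed=sub["qpcr"],
    )

    paths = {
        "expression": outdir / "expression.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "proteins": outdir / "proteins.fasta",
        "domains": outdir / "domains.tsv",
        "hits": outdir / "hits.tsv",
        "ct": outdir / "qpcr_ct.tsv",
        "truth": outdir / "ground_truth.json",
    }
    expr.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    coupled.values.rename_axis("metabolite_id").to_csv(paths["metabolites"], sep="\t")
    with open(paths["proteins"], "w") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n{seq}\n")
    domains.to_csv(paths["domains"], sep="\t", index=False)
    hits.to_csv(paths["hits"], sep="\t", index=False)
    ct.to_csv(paths["ct"], sep="\t", index=False)
    truth = {
        "rho1": coupled.truth.rho1,
        "residual_sd": coupled.truth.residual_sd,
        "y_loadings": list(coupled.truth.y_loadings),
        "gene_metabolite_r": coupled.truth.gene_metabolite_r.round(6).to_dict(),
        "regulation_classes": {g.gene_id: g.regulation_class for g in config.gene_specs},
        "peak_folds": {g.gene_id: g.peak_fold for g in config.gene_specs},
        "planted_families": domains.attrs.get("planted_families", {}),
        "seed": seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
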