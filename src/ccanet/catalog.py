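"""AP2/ERF superfamily cataloguing.

Homology-hit filtering, family assignment from domain architecture
(AP2 = two AP2 domains, RAV = AP2 + B3, single-AP2 proteins split into ERF
vs DREB by signature residues, Soloist flagged upstream), duplicated-gene
detection by global-alignment identity, and ProtParam-style protein
physicochemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices  # noqa: F401 (aligner only)
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import brentq

__all__ = [
    "FAMILY_NAMES",
    "FamilyCounts",
    "DuplicatePair",
    "DuplicationSummary",
    "PhysicoProps",
    "filter_homology_hits",
    "classify_family",
    "tally_families",
    "detect_duplicates",
    "summarize_duplicates",
    "compute_physicochemical",
    "read_fasta",
    "read_hit_table",
    "read_domain_table",
    "catalog_table",
]

FAMILY_NAMES = ("ERF", "DREB", "AP2", "RAV", "Soloist", "unclassified")

HIT_COLUMNS = ["query_id", "subject_id", "evalue", "bitscore", "aln_length"]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# default ERF/DREB discriminator: residues at AP2-domain positions 14 and 19
DEFAULT_SIGNATURES: Mapping[str, tuple[str, str]] = {"DREB": ("A", "D"), "ERF": ("V", "E")}


# ---------------------------------------------------------------------------
# homology filtering


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST-tabular-style TSV (qseqid, sseqid, evalue, bitscore, length)."""
    df = pd.read_csv(path, sep="\t")
    rename = dict(zip(["qseqid", "sseqid", "length"], ["query_id", "subject_id", "aln_length"]))
    df = df.rename(columns=rename)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return df[HIT_COLUMNS]


def filter_homology_hits(
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_bitscore: float = 100.0,
    min_aln_length: int = 100,
) -> pd.DataFrame:
    """Retain hits with evalue <= max_evalue, bitscore >= min_bitscore and
    alignment length >= min_aln_length (all cutoffs inclusive on the keep
    side), and mark each query's best surviving hit.

    Best hit per query = highest bitscore, ties by lowest evalue, then
    lexicographic subject id.  Malformed rows (missing fields, negative
    evalue) are rejected with their row number.
    """
    if min(max_evalue, min_bitscore, min_aln_length) <= 0:
        raise ValueError("thresholds must be positive")
    df = hits.copy()
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    for i, row in enumerate(df.itertuples(index=False)):
        if any(pd.isna(v) for v in row):
            raise ValueError(f"malformed hit record at row {i}: missing field")
        if row.evalue < 0:
            raise ValueError(f"malformed hit record at row {i}: negative evalue")
        if row.aln_length < 1:
            raise ValueError(f"malformed hit record at row {i}: aln_length < 1")
    keep = (
        (df["evalue"] <= max_evalue)
        & (df["bitscore"] >= min_bitscore)
        & (df["aln_length"] >= min_aln_length)
    )
    out = df.loc[keep].copy()
    if len(out):
        ranked = out.sort_values(
            ["query_id", "bitscore", "evalue", "subject_id"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        best_idx = ranked.groupby("query_id", sort=False).head(1).index
        out["best_hit"] = out.index.isin(best_idx)
    else:
        out["best_hit"] = pd.Series(dtype=bool)
    return out


# ---------------------------------------------------------------------------
# family classification


def read_domain_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    need = {"protein_id", "domain_type", "start", "end"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    return df


def classify_family(
    domains: pd.DataFrame | Iterable[Mapping],
    soloist_flag: bool = False,
    signatures: Mapping[str, tuple[str, str]] = DEFAULT_SIGNATURES,
) -> str:
    """Assign one protein's family from its domain annotations.

    Rules: two or more AP2 domains -> AP2; exactly one AP2 plus a B3 -> RAV;
    ``soloist_flag`` -> Soloist; exactly one AP2 and no B3 -> ERF or DREB by
    the signature residues at AP2 positions 14/19 (nearest signature when
    neither matches exactly, tie -> ERF); no AP2 domain -> unclassified.
    """
    df = pd.DataFrame(list(domains) if not isinstance(domains, pd.DataFrame) else domains)
    if len(df) and df["protein_id"].nunique() > 1:
        raise ValueError(f"domains span multiple proteins: {sorted(df['protein_id'].unique())}")
    n_ap2 = int((df["domain_type"] == "AP2").sum()) if len(df) else 0
    n_b3 = int((df["domain_type"] == "B3").sum()) if len(df) else 0
    pid = df["protein_id"].iloc[0] if len(df) else "<no-domain protein>"
    if soloist_flag:
        if n_ap2 >= 2:
            raise ValueError(f"{pid}: soloist flag conflicts with {n_ap2} AP2 domains")
        return "Soloist"
    if n_ap2 >= 2:
        return "AP2"
    if n_ap2 == 1 and n_b3 >= 1:
        return "RAV"
    if n_ap2 == 0:
        return "unclassified"
    ap2 = df[df["domain_type"] == "AP2"].iloc[0]
    r14 = str(ap2.get("residue14", "") or "")
    r19 = str(ap2.get("residue19", "") or "")
    best_fam, best_score = None, -1
    for fam in sorted(signatures):  # deterministic iteration
        s14, s19 = signatures[fam]
        score = int(r14 == s14) + int(r19 == s19)
        better = score > best_score or (
            score == best_score and fam == "ERF" and best_fam != "ERF"
        )
        if better:
            best_fam, best_score = fam, score
    return best_fam if best_fam is not None else "unclassified"


def classify_all(
    domains: pd.DataFrame,
    soloist_ids: Iterable[str] = (),
    signatures: Mapping[str, tuple[str, str]] = DEFAULT_SIGNATURES,
    protein_ids: Iterable[str] | None = None,
) -> pd.Series:
    """Family label per protein (index = protein_id).

    ``protein_ids`` adds proteins with no domain rows (labelled unclassified);
    a ``soloist`` column in the table is honoured alongside ``soloist_ids``.
    """
    soloists = set(soloist_ids)
    if "soloist" in domains.columns:
        soloists |= set(domains.loc[domains["soloist"].astype(bool), "protein_id"])
    labels: dict[str, str] = {}
    for pid, sub in domains.groupby("protein_id", sort=True):
        labels[pid] = classify_family(sub, soloist_flag=pid in soloists, signatures=signatures)
    for pid in protein_ids or ():
        labels.setdefault(pid, "Soloist" if pid in soloists else "unclassified")
    return pd.Series(labels, name="family").sort_index()


@dataclass(frozen=True)
class FamilyCounts:
    counts: dict[str, int]
    total: int


def tally_families(labels: Iterable[str] | pd.Series) -> FamilyCounts:
    """Count proteins per family; ``total`` includes unclassified."""
    values = list(labels.values if isinstance(labels, pd.Series) else labels)
    if not values:
        raise ValueError("no family labels to tally")
    unknown = set(values) - set(FAMILY_NAMES)
    if unknown:
        raise ValueError(f"unknown family labels: {sorted(unknown)}")
    counts = {fam: values.count(fam) for fam in FAMILY_NAMES}
    return FamilyCounts(counts=counts, total=len(values))


# ---------------------------------------------------------------------------
# duplicated genes


@dataclass(frozen=True)
class DuplicatePair:
    id1: str
    id2: str
    identity_pct: float
    evalue: float = float("nan")


@dataclass(frozen=True)
class DuplicationSummary:
    n_pairs: int
    n_distinct_genes: int


def _make_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_identity_pct(
    seq1: str, seq2: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Percent identity over all columns of the optimal global alignment.

    Gap columns count against identity, so 100 means a gap-free exact match.
    """
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(seq1, seq2)[0]
    identities = aln.counts().identities
    return 100.0 * identities / aln.length


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def detect_duplicates(
    proteins: Mapping[str, str],
    min_identity_pct: float = 95.0,
    max_evalue: float = 1e-10,
    hits: pd.DataFrame | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[DuplicatePair]:
    """Report unordered protein pairs whose global-alignment identity reaches
    ``min_identity_pct``, sorted by identity descending (ties by id pair).

    When a hit table of all-vs-all E-values is supplied, pairs must also
    satisfy ``evalue < max_evalue``; without one, identity alone decides and
    the reported evalue is NaN.
    """
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    for pid, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty sequence for {pid!r}")
        bad = set(seq) - STANDARD_AA
        if bad:
            raise ValueError(f"non-amino-acid characters in {pid!r}: {sorted(bad)}")
    evalue_of: dict[frozenset, float] = {}
    if hits is not None:
        for row in hits.itertuples(index=False):
            key = frozenset((row.query_id, row.subject_id))
            evalue_of[key] = min(evalue_of.get(key, math.inf), row.evalue)
    out: list[DuplicatePair] = []
    for i, id1 in enumerate(ids):
        for id2 in ids[i + 1 :]:
            ev = evalue_of.get(frozenset((id1, id2)), float("nan"))
            if hits is not None and not (ev < max_evalue):
                continue
            ident = global_identity_pct(proteins[id1], proteins[id2], match, mismatch, gap)
            if ident >= min_identity_pct:
                out.append(DuplicatePair(id1, id2, ident, ev))
    out.sort(key=lambda p: (-p.identity_pct, p.id1, p.id2))
    return out


def summarize_duplicates(pairs: Sequence[DuplicatePair] | pd.DataFrame) -> DuplicationSummary:
    """Number of pairs and of distinct genes participating in any pair."""
    if isinstance(pairs, pd.DataFrame):
        ids = pd.concat([pairs["id1"], pairs["id2"]]).unique()
        return DuplicationSummary(n_pairs=len(pairs), n_distinct_genes=len(ids))
    genes = {g for p in pairs for g in (p.id1, p.id2)}
    return DuplicationSummary(n_pairs=len(pairs), n_distinct_genes=len(genes))


# ---------------------------------------------------------------------------
# physicochemistry

# mole-percent weights for Ala, Val, Ile+Leu in the aliphatic index
_ALIPHATIC_WEIGHTS = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}


@dataclass(frozen=True)
class PhysicoProps:
    length_aa: int
    mol_weight_Da: float
    pI: float
    instability_index: float
    aliphatic_index: float
    gravy: float


def net_charge(seq: str, ph: float) -> float:
    """Net protein charge at a given pH under the Bjellqvist pKa model."""
    return IsoelectricPoint(seq).charge_at_pH(ph)


def compute_physicochemical(seq: str) -> PhysicoProps:
    """ProtParam-style descriptors for one protein sequence.

    Average-mass molecular weight, isoelectric point (root of the Bjellqvist
    net-charge curve, |charge| < 1e-6), Guruprasad instability index,
    aliphatic index (mole-percent Ala + 2.9 Val + 3.9 (Ile + Leu)) and
    Kyte-Doolittle GRAVY.  Ambiguous residue codes (B, Z, X, ...) are
    rejected.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"ambiguous or invalid residue codes: {sorted(bad)}")
    pa = ProteinAnalysis(seq)
    length = len(seq)
    pI = brentq(lambda ph: net_charge(seq, ph), 0.0, 14.0, xtol=1e-8)
    assert abs(net_charge(seq, pI)) < 1e-4
    mole_pct = {aa: 100.0 * seq.count(aa) / length for aa in _ALIPHATIC_WEIGHTS}
    aliphatic = sum(w * mole_pct[aa] for aa, w in _ALIPHATIC_WEIGHTS.items())
    instability = pa.instability_index() if length >= 2 else 0.0
    return PhysicoProps(
        length_aa=length,
        mol_weight_Da=pa.molecular_weight(),
        pI=float(pI),
        instability_index=float(instability),
        aliphatic_index=float(aliphatic),
        gravy=float(pa.gravy()),
    )


# ---------------------------------------------------------------------------
# assembled catalogue


def catalog_table(
    proteins: Mapping[str, str],
    domains: pd.DataFrame,
    hits: pd.DataFrame | None = None,
    soloist_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """One catalogue row per protein: family plus physicochemical properties.

    When a hit table is given, proteins are first restricted to queries that
    survive :func:`filter_homology_hits` at its default thresholds.
    """
    keep = set(proteins)
    if hits is not None:
        surviving = filter_homology_hits(hits)
        keep &= set(surviving["query_id"])
    labels = classify_all(domains, soloist_ids=soloist_ids, protein_ids=keep)
    rows = []
    for pid in sorted(keep):
        props = compute_physicochemical(proteins[pid])
        rows.append(
            {
                "protein_id": pid,
                "family": labels.get(pid, "unclassified"),
                "length_aa": props.length_aa,
                "mol_weight_Da": props.mol_weight_Da,
                "pI": props.pI,
                "instability_index": props.instability_index,
                "aliphatic_index": props.aliphatic_index,
                "gravy": props.gravy,
            }
        )
    return pd.DataFrame(rows)
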