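"""Kinase-catalyzed-biotinylation screen analytics.

The screen compares three reactions run on isolated FA-cytoskeleton
fractions over four trials: (1) kinase with plain ATP (unlabeled control),
(2) ATP-biotin without added kinase (negative control), (3) ATP-biotin with
kinase (experimental).  Proteins enriched in or exclusive to the unlabeled
control are removed; per-trial fold enrichment is the experimental intensity
divided by the negative-control intensity; hit lists are called by an
enrichment threshold met in a minimum number of trials (canonically >= 1.5-
or >= 6.0-fold in 2 of 4 trials).

Zero intensity means "not detected" (the usual label-free-quantitation
convention).  A trial with experimental signal but no negative-control
signal is maximal enrichment and is flagged +inf — it exceeds any threshold;
a trial with neither signal is not evaluable.  Both conventions are
switchable (``count_exclusive``).

Candidate substrates can be screened for the basophilic PKA consensus around
Ser/Thr phosphoacceptors: R-R-x-S/T (strong), K-R-x-S/T or R-x-x-S/T
(moderate), typically followed by a hydrophobic residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

CONDITIONS = ("ctrl_ATP_PKA", "neg_ATPbiotin_noPKA", "exp_ATPbiotin_PKA")
_CONTAMINANT_PREFIXES = ("CON__", "REV__")

ID_COLUMNS = ("accession", "gene")


def condition_columns(table: pd.DataFrame, condition: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(condition + "_t")]
    return sorted(cols, key=lambda c: int(c.rsplit("_t", 1)[1]))


def n_trials(table: pd.DataFrame) -> int:
    return len(condition_columns(table, CONDITIONS[0]))


def load_quant_table(path, column_map: dict | str | None = None) -> pd.DataFrame:
    """Read a protein quantitation table (TSV/CSV, one row per protein).

    ``column_map`` maps the file's columns onto the screen layout::

        accession: <column with unique protein accessions>
        gene: <column with gene symbols>          # optional
        columns:
          <intensity column>: [<condition>, <trial number>]

    where condition is one of ``ctrl_ATP_PKA``, ``neg_ATPbiotin_noPKA``,
    ``exp_ATPbiotin_PKA``.  A path to a YAML file is accepted.  When
    ``column_map`` is None the file must already use the canonical layout
    (``accession``, optional ``gene``, ``<condition>_t<trial>``).

    Missing intensities read as 0 (not detected); contaminant and
    reverse-decoy rows (accession prefix ``CON__`` / ``REV__``) are dropped;
    duplicate accessions are an error.
    """
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if isinstance(column_map, str):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    if column_map is not None:
        rename = {column_map["accession"]: "accession"}
        if column_map.get("gene"):
            rename[column_map["gene"]] = "gene"
        for src, (cond, trial) in column_map["columns"].items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in column map")
            if src not in df.columns:
                raise ValueError(f"mapped column {src!r} not present in table")
            rename[src] = f"{cond}_t{int(trial)}"
        df = df.rename(columns=rename)
    if "accession" not in df.columns:
        raise ValueError("no accession column mapped")
    if "gene" not in df.columns:
        df["gene"] = ""
    value_cols = [c for cond in CONDITIONS for c in condition_columns(df, cond)]
    if not value_cols:
        raise ValueError("no intensity columns mapped to any condition")
    df = df[~df["accession"].astype(str).str.startswith(_CONTAMINANT_PREFIXES)]
    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].unique()
        raise ValueError(f"duplicate accessions: {list(dupes)[:5]}")
    df[value_cols] = df[value_cols].fillna(0.0).astype(float)
    return df[["accession", "gene", *value_cols]].reset_index(drop=True)


def filter_control_enriched(table: pd.DataFrame) -> pd.DataFrame:
    """Drop proteins enriched in or exclusive to the unlabeled control.

    A protein is removed when its unlabeled-control intensity exceeds its
    experimental intensity in a majority of the trials where both were
    detected, or when it was detected only in the unlabeled control.
    """
    ctrl = table[condition_columns(table, "ctrl_ATP_PKA")].to_numpy()
    exp = table[condition_columns(table, "exp_ATPbiotin_PKA")].to_numpy()
    neg = table[condition_columns(table, "neg_ATPbiotin_noPKA")].to_numpy()
    both = (ctrl > 0) & (exp > 0)
    higher = (ctrl > exp) & both
    majority = (higher.sum(axis=1) * 2) > both.sum(axis=1)
    exclusive = (ctrl > 0).any(axis=1) & ~((exp > 0).any(axis=1) | (neg > 0).any(axis=1))
    return table[~(majority | exclusive)].reset_index(drop=True)


def compute_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial fold enrichment: experimental / negative-control intensity.

    Detected experimental signal over an undetected negative control is
    flagged +inf (maximal enrichment); a trial where neither was detected is
    NaN (not evaluable).  Returns accession/gene plus ``enrichment_t<k>``
    columns and ``n_trials_evaluable``.
    """
    exp = table[condition_columns(table, "exp_ATPbiotin_PKA")].to_numpy()
    neg = table[condition_columns(table, "neg_ATPbiotin_noPKA")].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = exp / neg
    enr = np.where((neg == 0) & (exp > 0), np.inf, enr)
    enr = np.where((neg == 0) & (exp == 0), np.nan, enr)
    out = table[["accession", "gene"]].copy()
    for k in range(enr.shape[1]):
        out[f"enrichment_t{k + 1}"] = enr[:, k]
    out["n_trials_evaluable"] = np.isfinite(enr).sum(axis=1) + np.isinf(enr).sum(axis=1)
    return out


@dataclass(frozen=True)
class HitList:
    threshold: float
    min_trials: int
    total_trials: int
    hits: pd.DataFrame  # accession, gene, per-trial enrichment, n_passing_trials

    @property
    def accessions(self) -> list[str]:
        return list(self.hits["accession"])


def call_hits(
    enrichment: pd.DataFrame,
    threshold: float,
    min_trials: int = 2,
    count_exclusive: bool = True,
) -> HitList:
    """Call hits: enrichment >= threshold in at least ``min_trials`` trials.

    +inf trials (experimental-only detection) count toward the requirement
    when ``count_exclusive`` (default); NaN trials never do.  Hits are sorted
    by descending median finite enrichment, ties by accession.
    """
    cols = [c for c in enrichment.columns if c.startswith("enrichment_t")]
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not (1 <= min_trials <= len(cols)):
        raise ValueError("min_trials out of range")
    vals = enrichment[cols].to_numpy()
    passing = vals >= threshold
    if not count_exclusive:
        passing &= np.isfinite(vals)
    passing &= ~np.isnan(vals)
    n_pass = passing.sum(axis=1)
    is_hit = n_pass >= min_trials
    hits = enrichment[is_hit].copy()
    hits["n_passing_trials"] = n_pass[is_hit]
    finite = np.where(np.isfinite(vals[is_hit]), vals[is_hit], np.nan)
    any_finite = ~np.all(np.isnan(finite), axis=1)
    med = np.full(finite.shape[0], np.inf)  # exclusively +inf trials: maximal
    med[any_finite] = np.nanmedian(finite[any_finite], axis=1)
    hits["median_enrichment"] = med
    hits = hits.sort_values(
        ["median_enrichment", "accession"], ascending=[False, True]
    ).reset_index(drop=True)
    return HitList(
        threshold=threshold,
        min_trials=min_trials,
        total_trials=len(cols),
        hits=hits,
    )


@dataclass(frozen=True)
class MotifHit:
    accession: str
    position: int  # 1-based index of the S/T phosphoacceptor
    window: str  # residues -4..+1 around the site ('-' beyond termini)
    tier: str  # "strong" or "moderate"
    score: float


_HYDROPHOBIC = set("AVLIFMW")
_TIER_ORDER = {"moderate": 0, "strong": 1}


def _site_score(m3: str, m2: str, p1: str) -> float:
    """Weighted fraction of matched consensus determinants in [0, 1]:
    basic at -3 (R full, K partial), R at -2, hydrophobic at +1."""
    w3 = 1.0 if m3 == "R" else (0.7 if m3 == "K" else 0.0)
    w2 = 1.0 if m2 == "R" else 0.0
    wp = 0.5 if p1 in _HYDROPHOBIC else 0.0
    return (w3 + w2 + wp) / 2.5


def scan_pka_motifs(
    sequence: str, accession: str = "", min_tier: str = "moderate"
) -> list[MotifHit]:
    """Scan a protein sequence for PKA consensus phosphosites.

    Every Ser/Thr is examined against its -4..+1 window: strong sites have
    Arg at both -3 and -2 (R-R-x-S/T); moderate sites have Lys at -3 with
    Arg at -2 (K-R-x-S/T) or Arg at -3 alone (R-x-x-S/T).  ``min_tier``
    restricts the output ("strong" keeps only strong sites).  Unknown
    residues (X) never match; an empty sequence yields an empty list.
    """
    if min_tier not in _TIER_ORDER:
        raise ValueError("min_tier must be 'moderate' or 'strong'")
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for i, aa in enumerate(seq):
        if aa not in "ST":
            continue
        m3 = seq[i - 3] if i >= 3 else "-"
        m2 = seq[i - 2] if i >= 2 else "-"
        p1 = seq[i + 1] if i + 1 < len(seq) else "-"
        if m3 == "R" and m2 == "R":
            tier = "strong"
        elif (m3 == "K" and m2 == "R") or m3 == "R":
            tier = "moderate"
        else:
            continue
        if _TIER_ORDER[tier] < _TIER_ORDER[min_tier]:
            continue
        window = "".join(
            seq[j] if 0 <= j < len(seq) else "-" for j in range(i - 4, i + 2)
        )
        hits.append(
            MotifHit(
                accession=accession,
                position=i + 1,
                window=window,
                tier=tier,
                score=_site_score(m3, m2, p1),
            )
        )
    return hits


def scan_fasta(path, min_tier: str = "moderate") -> list[MotifHit]:
    """Scan every record of a FASTA file for PKA consensus phosphosites."""
    from Bio import SeqIO

    hits: list[MotifHit] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        hits.extend(scan_pka_motifs(str(rec.seq), accession=rec.id, min_tier=min_tier))
    return hits


def motif_hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": h.accession,
                "position": h.position,
                "window": h.window,
                "tier": h.tier,
                "score": h.score,
            }
            for h in hits
        ],
        columns=["accession", "position", "window", "tier", "score"],
    )
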