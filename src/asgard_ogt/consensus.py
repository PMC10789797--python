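"""Consensus of ancestral sequence reconstructions from multiple ASR engines.

Different reconstruction engines (e.g. empirical-Bayes in IQ-TREE, FastML,
PAML) inferring the same ancestral node typically agree at most alignment
columns but disagree at a minority of sites. This module combines several
pre-aligned reconstructions, each with per-site posterior probabilities
(PP), into a single consensus by per-column majority vote with deterministic
tie-breaking:

1. unanimous column -> keep the state;
2. otherwise the state with the most votes wins (the gap ``-`` is a votable
   state);
3. vote ties break toward the state with the highest PP among its backers
   (a gap carries no PP and counts as 0, so residues with evidence beat
   gaps);
4. remaining ties break lexicographically on the state character.

An optional reference ("neighbor") sequence can instead resolve
disagreements toward the state that sequence carries at the column,
emulating manual curation against closely related extant sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_STATES = set(AMINO_ACIDS) | {GAP}


@dataclass(frozen=True)
class AncestralReconstruction:
    """One engine's aligned ancestral sequence with per-column posteriors.

    ``site_pp[i]`` is the posterior probability of the state at aligned
    column ``i``; gap columns carry no probability (stored as NaN).
    """

    method_id: str
    sequence: str
    site_pp: np.ndarray

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        pp = np.asarray(self.site_pp, dtype=float)
        object.__setattr__(self, "site_pp", pp)
        bad = set(seq) - VALID_STATES
        if bad:
            raise ValueError(f"invalid residue characters in {self.method_id!r}: {sorted(bad)}")
        if len(seq) != pp.size:
            raise ValueError(
                f"{self.method_id!r}: sequence length {len(seq)} != PP length {pp.size}"
            )
        finite = pp[np.isfinite(pp)]
        if np.any(finite < 0) or np.any(finite > 1):
            raise ValueError("posterior probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus ancestral sequence over aligned columns.

    ``aligned_sequence`` keeps gap columns; ``sequence`` is the unaligned
    export with gap-winning columns removed. ``site_pp`` is the chosen-state
    PP per aligned column (NaN where the consensus is a gap); ``mean_pp``
    averages over non-gap consensus columns.
    """

    aligned_sequence: str
    site_pp: np.ndarray
    disagreement_sites: tuple

    @property
    def sequence(self) -> str:
        return self.aligned_sequence.replace(GAP, "")

    @property
    def mean_pp(self) -> float:
        return mean_posterior(self)


def _chosen_pp(recs: Sequence[AncestralReconstruction], col: int, state: str) -> float:
    """Maximum PP among inputs carrying `state` at column `col`; 0 for gaps."""
    if state == GAP:
        return float("nan")
    best = 0.0
    for r in recs:
        if r.sequence[col] == state and np.isfinite(r.site_pp[col]):
            best = max(best, float(r.site_pp[col]))
    return best


def consensus_sequence(
    recs: Sequence[AncestralReconstruction],
    reference: Optional[str] = None,
) -> ConsensusResult:
    """Column-wise majority-vote consensus of >= 2 aligned reconstructions.

    ``reference`` optionally supplies a neighbor sequence of the aligned
    length; at non-unanimous columns a state present in the reference wins
    outright before the vote/PP/lexicographic cascade applies.
    """
    if len(recs) < 2:
        raise ValueError("consensus needs at least 2 reconstructions")
    length = len(recs[0])
    if any(len(r) != length for r in recs):
        raise ValueError(
            "reconstructions have unequal aligned lengths; align them first "
            "(alignment is outside this tool's scope)"
        )
    if reference is not None:
        reference = reference.upper()
        if len(reference) != length:
            raise ValueError("reference sequence must match the aligned length")
        bad = set(reference) - VALID_STATES
        if bad:
            raise ValueError(f"invalid residue characters in reference: {sorted(bad)}")

    chars = []
    pps = np.full(length, np.nan)
    disagreements = []
    for col in range(length):
        states = [r.sequence[col] for r in recs]
        uniq = sorted(set(states))
        if len(uniq) == 1:
            chosen = uniq[0]
        else:
            disagreements.append(col)
            chosen = None
            if reference is not None and reference[col] in uniq:
                chosen = reference[col]
            if chosen is None:
                # majority, then PP, then lexicographic ('-' sorts first)
                def rank(s: str):
                    votes = states.count(s)
                    pp = _chosen_pp(recs, col, s)
                    pp = 0.0 if not np.isfinite(pp) else pp
                    return (-votes, -pp, s)

                chosen = min(uniq, key=rank)
        chars.append(chosen)
        if chosen != GAP:
            pps[col] = _chosen_pp(recs, col, chosen)
    return ConsensusResult(
        aligned_sequence="".join(chars),
        site_pp=pps,
        disagreement_sites=tuple(disagreements),
    )


def mean_posterior(result: ConsensusResult) -> float:
    """Arithmetic mean of the chosen-state PP over non-gap consensus columns."""
    mask = np.array([c != GAP for c in result.aligned_sequence])
    if not mask.any():
        raise ValueError("consensus is all gaps; mean posterior undefined")
    return float(np.nanmean(result.site_pp[mask]))


def disagreement_report(
    recs: Sequence[AncestralReconstruction], result: ConsensusResult
) -> pd.DataFrame:
    """One row per disagreement column: each method's state, the chosen state and PP.

    Supports manual review of the sites where the engines differ (the sites a
    curator would inspect against neighboring extant sequences).
    """
    rows = []
    for col in result.disagreement_sites:
        row = {"column": col}
        for r in recs:
            row[f"state_{r.method_id}"] = r.sequence[col]
        row["chosen_state"] = result.aligned_sequence[col]
        pp = result.site_pp[col]
        row["chosen_pp"] = float(pp) if np.isfinite(pp) else np.nan
        rows.append(row)
    cols = ["column"] + [f"state_{r.method_id}" for r in recs] + ["chosen_state", "chosen_pp"]
    return pd.DataFrame(rows, columns=cols)


def read_reconstructions(
    fasta_path: Union[str, Path], pp_paths: dict
) -> list[AncestralReconstruction]:
    """Load reconstructions from an aligned FASTA plus per-method PP tables.

    ``pp_paths`` maps each FASTA record id to a TSV with columns
    ``column`` (0-based aligned index) and ``pp``; columns absent from the
    table (gaps) get NaN.
    """
    recs = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in pp_paths:
            raise ValueError(f"no PP table supplied for method {record.id!r}")
        seq = str(record.seq)
        pp = np.full(len(seq), np.nan)
        table = pd.read_csv(pp_paths[record.id], sep="\t")
        if not {"column", "pp"} <= set(table.columns):
            raise ValueError(f"PP table for {record.id!r} needs columns 'column' and 'pp'")
        idx = table["column"].to_numpy(dtype=int)
        if np.any(idx < 0) or np.any(idx >= len(seq)):
            raise ValueError(f"PP table for {record.id!r} has out-of-range columns")
        pp[idx] = table["pp"].to_numpy(dtype=float)
        recs.append(AncestralReconstruction(record.id, seq, pp))
    return recs


def write_consensus(
    result: ConsensusResult,
    recs: Sequence[AncestralReconstruction],
    fasta_path: Union[str, Path],
    report_path: Union[str, Path],
    name: str = "consensus",
) -> None:
    """Write the unaligned consensus FASTA and the per-site TSV report."""
    record = SeqRecord(Seq(result.sequence), id=name, description=f"mean_pp={result.mean_pp:.4f}")
    SeqIO.write([record], str(fasta_path), "fasta")
    disagreement_report(recs, result).to_csv(report_path, sep="\t", index=False)
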