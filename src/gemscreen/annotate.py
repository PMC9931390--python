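"""Mutation classification from Sanger consensus sequences.

Each consensus read of a resistance locus (here the nucleoside-permease
CDS) is aligned against the reference coding sequence and classified:
point substitutions are translated and called missense/nonsense/silent,
alignment gaps become indels (with frameshift flagging), and a long
insertion or a truncated high-identity local alignment is reported as a
transposon/junction event.  A rank-sum test asks whether missense
positions are biased toward evolutionarily conserved residues.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "MutationCall",
    "align_and_classify",
    "spectrum",
    "conservation_bias_test",
]

#: insertions/deletions at least this long are treated as transposon or
#: junction events rather than short indels
TRANSPOSON_MIN_LEN = 30

MUTATION_TYPES = ("none", "missense", "nonsense", "indel",
                  "transposon/junction", "unassigned")


@dataclass(frozen=True)
class MutationCall:
    """Classification of one query sequence against the reference CDS."""

    type: str
    nt_position: int | None = None  # 1-based on the CDS
    protein_position: int | None = None
    ref_residue: str | None = None
    alt_residue: str | None = None
    indel_length: int | None = None
    frameshift: bool | None = None
    note: str = ""


def _make_aligner(local: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    if local:
        aligner.mode = "local"
    else:
        aligner.mode = "global"
        # Free end gaps on the query only: vector/primer sequence flanking
        # the consensus is soft-clipped, while unaligned reference ends stay
        # penalized so internal insertions are not silently clipped away.
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
    return aligner


def align_and_classify(query: str, ref_cds: str) -> MutationCall:
    """Globally align ``query`` to ``ref_cds`` and classify the difference.

    The reference must be a complete CDS (length divisible by 3, ATG/GTG/TTG
    start).  End gaps are free, so up to ~30 bp of vector sequence on either
    side of the query is soft-clipped.  Internal gaps < 30 bp are indels;
    longer insertions, or a high-identity local alignment covering < 80% of
    the query with the remainder unalignable, are transposon/junction calls.
    """
    query = str(query).upper().replace("U", "T")
    ref_cds = str(ref_cds).upper()
    if len(ref_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    if ref_cds[:3] not in ("ATG", "GTG", "TTG"):
        raise ValueError("reference CDS must begin with a start codon")
    if len(query) < 50:
        return MutationCall("unassigned", note="query shorter than 50 bp")

    aln = _make_aligner().align(ref_cds, query)[0]
    ref_idx, qry_idx = aln.aligned  # blocks on target (ref) / query

    events = _collect_events(ref_cds, query, ref_idx, qry_idx)

    # identity over the reference span actually covered
    matched = sum(1 for e in events if e[0] == "match")
    covered = matched + sum(1 for e in events if e[0] == "sub")
    identity = matched / covered if covered else 0.0

    if identity < 0.5 or covered < 50:
        loc = _make_aligner(local=True).align(ref_cds, query)[0]
        qspan = loc.aligned[1]
        if len(qspan):
            qlen_aln = int(sum(b - a for a, b in qspan))
            lid = _local_identity(loc, ref_cds, query)
            if lid >= 0.9 and qlen_aln < 0.8 * len(query):
                pos = int(loc.aligned[0][0][0]) + 1
                return MutationCall("transposon/junction", nt_position=pos,
                                    note="truncated local alignment")
        return MutationCall("unassigned", note=f"identity {identity:.2f} below 0.5")

    # A large soft-clipped query chunk means part of the consensus does not
    # belong to the locus at all (insertion element or new junction); small
    # clips are vector/primer carry-over.
    clip = max(int(qry_idx[0][0]), len(query) - int(qry_idx[-1][1]))
    if clip >= 40:
        return MutationCall("transposon/junction", nt_position=int(ref_idx[0][0]) + 1,
                            note=f"{clip} bp of query unalignable at one end")

    # large insertion/deletion -> transposon/junction
    for kind, rpos, payload in events:
        if kind in ("ins", "del") and abs(payload) >= TRANSPOSON_MIN_LEN:
            return MutationCall("transposon/junction", nt_position=rpos + 1,
                                indel_length=abs(payload),
                                note=f"{kind} of {abs(payload)} bp")
    # short indel
    for kind, rpos, payload in events:
        if kind in ("ins", "del"):
            length = abs(payload)
            return MutationCall("indel", nt_position=rpos + 1, indel_length=length,
                                frameshift=bool(length % 3))
    # substitutions: classify by codon impact, worst effect first
    subs = [(rpos, alt) for kind, rpos, alt in events if kind == "sub"]
    best: MutationCall | None = None
    for rpos, alt in subs:
        call = _classify_substitution(ref_cds, rpos, alt)
        if call.type == "nonsense":
            return call
        if call.type == "missense" and (best is None or best.type != "missense"):
            best = call
    if best is not None:
        return best
    return MutationCall("none")


def _collect_events(ref: str, qry: str, ref_idx, qry_idx):
    """Walk aligned blocks, yielding match/sub/ins/del events on the ref."""
    events = []
    for b, (rblock, qblock) in enumerate(zip(ref_idx, qry_idx)):
        if b > 0:
            rgap = rblock[0] - ref_idx[b - 1][1]
            qgap = qblock[0] - qry_idx[b - 1][1]
            if rgap > 0:
                events.append(("del", int(ref_idx[b - 1][1]), -rgap))
            if qgap > 0:
                events.append(("ins", int(ref_idx[b - 1][1]), qgap))
        for off in range(rblock[1] - rblock[0]):
            r, q = ref[rblock[0] + off], qry[qblock[0] + off]
            if r == q:
                events.append(("match", rblock[0] + off, r))
            else:
                events.append(("sub", rblock[0] + off, q))
    return events


def _local_identity(aln, ref: str, qry: str) -> float:
    matched = total = 0
    for rblock, qblock in zip(*aln.aligned):
        for off in range(rblock[1] - rblock[0]):
            total += 1
            if ref[rblock[0] + off] == qry[qblock[0] + off]:
                matched += 1
    return matched / total if total else 0.0


def _classify_substitution(ref_cds: str, rpos: int, alt: str) -> MutationCall:
    codon_i = rpos // 3
    codon = ref_cds[codon_i * 3: codon_i * 3 + 3]
    mut = codon[: rpos % 3] + alt + codon[rpos % 3 + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut).translate())
    if alt_aa == ref_aa:
        return MutationCall("none", nt_position=rpos + 1,
                            protein_position=codon_i + 1, note="silent")
    mtype = "nonsense" if alt_aa == "*" else "missense"
    return MutationCall(mtype, nt_position=rpos + 1, protein_position=codon_i + 1,
                        ref_residue=ref_aa, alt_residue=alt_aa)


def spectrum(calls) -> dict:
    """Tally of mutation types plus the fraction of mutated queries."""
    tally = {t: 0 for t in MUTATION_TYPES}
    for c in calls:
        tally[c.type] += 1
    total = sum(tally.values())
    mutated = total - tally["none"]
    tally["fraction_mutated"] = mutated / total if total else 0.0
    return tally


# ---------------------------------------------------------------------------
# Conservation bias


def conservation_bias_test(scores, mutated_positions, exclusive: bool = False
                           ) -> tuple[float, float]:
    """Rank-sum test for conservation bias of mutated residues.

    Compares conservation scores at ``mutated_positions`` (1-based) against
    the scores of all positions of the protein (the mutated positions are
    included in the background unless ``exclusive=True``), one-sided toward
    higher conservation.  Uses exact enumeration over all assignments for
    combined n <= 20 (valid under ties) and the tie-corrected normal
    approximation otherwise.  Returns ``(W, p)`` with ``W`` the rank sum of
    the mutated group.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(mutated_positions, dtype=int)
    if pos.size < 3:
        raise ValueError("need at least 3 mutated positions")
    if pos.min() < 1 or pos.max() > scores.size:
        raise ValueError("mutated positions outside the profile")
    x = scores[pos - 1]
    y = np.delete(scores, pos - 1) if exclusive else scores

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all conservation scores identical; test degenerate",
                      stacklevel=2)
        return float(stats.rankdata(pooled)[: x.size].sum()), 1.0

    ranks = stats.rankdata(pooled)
    W = float(ranks[: x.size].sum())

    n = pooled.size
    if n <= 20:
        p = _exact_ranksum_p(pooled, x.size, W)
    else:
        res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        p = float(res.pvalue)
    return W, p


def _exact_ranksum_p(pooled: np.ndarray, k: int, W_obs: float) -> float:
    """P(rank sum >= W_obs) by enumerating all k-subsets of the pooled
    values (handles ties exactly)."""
    ranks = stats.rankdata(pooled)
    tol = 1e-9
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), k):
        total += 1
        if ranks[list(comb)].sum() >= W_obs - tol:
            hits += 1
    return hits / total
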