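"""Column-wise sequence profiles, glocal profile alignment, and empirical E-values.

A :class:`ProfileModel` is a log-odds position-specific scoring model built
from a seed alignment.  Queries are aligned *glocally* (global in the profile,
local in the query: the whole profile must be traversed while query flanks
overhang free of charge) by dynamic programming with affine gap costs.  Raw
bit scores are converted to E-values by an empirical calibration against
residue-shuffled decoys, with an exponential fit to the upper tail of the
decoy score distribution.

Reference residue numbering is carried by the profile: every column under
which the designated reference row of the seed has a residue is mapped to
that residue's 1-based position in the ungapped reference sequence.  This is
the anchor for statements like "the residue at position 108".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
AMBIGUOUS = "X"

#: flat background over the 20 amino acids
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


class ProfileError(ValueError):
    """Raised on malformed seed alignments, profiles or queries."""


# ---------------------------------------------------------------------------
# Seed alignments
# ---------------------------------------------------------------------------


@dataclass
class SeedAlignment:
    """A gapped amino-acid alignment with a designated reference row.

    Parameters
    ----------
    rows
        ``(sequence_id, gapped_sequence)`` pairs; all gapped strings must
        have equal length and use the 20 amino acids plus ``-`` and ``X``.
    reference_row
        The ``sequence_id`` whose ungapped 1-based residue numbering anchors
        all downstream positional statements.
    """

    rows: list[tuple[str, str]]
    reference_row: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ProfileError("seed alignment is empty")
        width = len(self.rows[0][1])
        ids = set()
        allowed = set(AMINO_ACIDS) | {GAP, AMBIGUOUS}
        for sid, seq in self.rows:
            if len(seq) != width:
                raise ProfileError(f"row {sid!r} has length {len(seq)} != {width}")
            bad = set(seq) - allowed
            if bad:
                raise ProfileError(f"row {sid!r} contains invalid characters {sorted(bad)}")
            ids.add(sid)
        if self.reference_row not in ids:
            raise ProfileError(f"reference row {self.reference_row!r} absent from alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def reference_sequence(self) -> str:
        gapped = dict(self.rows)[self.reference_row]
        return gapped.replace(GAP, "")

    def reference_numbering(self) -> dict[int, int]:
        """Map 0-based column index -> 1-based reference residue number.

        Columns where the reference row carries a gap are absent from the map.
        """
        gapped = dict(self.rows)[self.reference_row]
        numbering: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(gapped):
            if ch != GAP:
                pos += 1
                numbering[col] = pos
        return numbering

    @classmethod
    def from_fasta(cls, path, reference_row: str | None = None) -> "SeedAlignment":
        from Bio import SeqIO

        rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if reference_row is None:
            if not rows:
                raise ProfileError(f"no sequences in {path}")
            reference_row = rows[0][0]
        return cls(rows=rows, reference_row=reference_row)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.rows:
                fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Profile model
# ---------------------------------------------------------------------------


@dataclass
class ProfileColumn:
    frequencies: np.ndarray  # shape (20,), sums to 1; includes pseudocounts
    log_odds: np.ndarray  # bits, log2(freq / background)
    is_match: bool
    counts: np.ndarray | None = None  # raw residue counts from the seed

    def emission_frequencies(self) -> np.ndarray:
        """Empirical column distribution (no pseudocount mass), for sampling."""
        if self.counts is not None and self.counts.sum() > 0:
            return self.counts / self.counts.sum()
        return self.frequencies


@dataclass
class ProfileModel:
    """Position-specific log-odds scoring model with reference numbering."""

    columns: list[ProfileColumn]
    background: np.ndarray
    consensus: str
    ref_number_of_column: dict[int, int]
    pseudocount_weight: float
    match_columns: list[int] = field(default_factory=list)

    @property
    def n_match(self) -> int:
        return len(self.match_columns)

    def match_log_odds(self) -> np.ndarray:
        """(n_match, 20) log-odds matrix over match columns."""
        return np.stack([self.columns[c].log_odds for c in self.match_columns])

    def column_for_ref(self, ref_number: int) -> int | None:
        for col, ref in self.ref_number_of_column.items():
            if ref == ref_number:
                return col
        return None

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "format": "iscutrace-profile",
            "version": 1,
            "pseudocount_weight": self.pseudocount_weight,
            "background": [round(float(x), 12) for x in self.background],
            "consensus": self.consensus,
            "ref_number_of_column": {str(k): v for k, v in self.ref_number_of_column.items()},
            "columns": [
                {
                    "frequencies": [round(float(x), 12) for x in c.frequencies],
                    "is_match": c.is_match,
                    "counts": None if c.counts is None else [float(x) for x in c.counts],
                }
                for c in self.columns
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ProfileModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "iscutrace-profile":
            raise ProfileError(f"{path} is not a profile document")
        background = np.asarray(doc["background"], dtype=float)
        columns = []
        for c in doc["columns"]:
            freq = np.asarray(c["frequencies"], dtype=float)
            with np.errstate(divide="ignore"):
                lo = np.log2(freq / background)
            counts = c.get("counts")
            columns.append(
                ProfileColumn(
                    freq,
                    lo,
                    bool(c["is_match"]),
                    counts=None if counts is None else np.asarray(counts, dtype=float),
                )
            )
        return cls(
            columns=columns,
            background=background,
            consensus=doc["consensus"],
            ref_number_of_column={int(k): int(v) for k, v in doc["ref_number_of_column"].items()},
            pseudocount_weight=float(doc["pseudocount_weight"]),
            match_columns=[i for i, c in enumerate(columns) if c.is_match],
        )


def build_profile(
    seed: SeedAlignment,
    alpha: float = 1.0,
    background: np.ndarray | None = None,
    match_gap_threshold: float = 0.5,
) -> ProfileModel:
    """Estimate a column-wise profile from a seed alignment.

    Per-column frequencies use background-weighted pseudocounts::

        f(a) = (count(a) + alpha * background(a)) / (n_ungapped + alpha)

    Columns whose gap fraction is >= ``match_gap_threshold`` (default 50%)
    are flagged non-match and excluded from scoring and consensus.  ``X``
    residues are treated as fully ambiguous: they count toward neither the
    residue counts nor the ungapped denominator.
    """
    if alpha < 0:
        raise ProfileError("alpha must be nonnegative")
    if background is None:
        background = UNIFORM_BACKGROUND.copy()
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise ProfileError("background must be 20 probabilities summing to 1")

    n_rows = len(seed.rows)
    columns: list[ProfileColumn] = []
    consensus_chars: list[str] = []
    match_columns: list[int] = []
    for col in range(seed.width):
        counts = np.zeros(20)
        n_gap = 0
        for _, seq in seed.rows:
            ch = seq[col]
            if ch == GAP:
                n_gap += 1
            elif ch != AMBIGUOUS:
                counts[AA_INDEX[ch]] += 1
        n_ungapped = counts.sum()
        denom = n_ungapped + alpha
        if denom == 0:
            freq = background.copy()
        else:
            freq = (counts + alpha * background) / denom
        with np.errstate(divide="ignore"):
            log_odds = np.log2(freq / background)
        is_match = (n_gap / n_rows) < match_gap_threshold
        columns.append(ProfileColumn(freq, log_odds, is_match, counts=counts))
        if is_match:
            match_columns.append(col)
            # argmax with alphabetical tie-break: np.argmax returns the first
            # index, and AMINO_ACIDS is alphabetically ordered
            consensus_chars.append(AMINO_ACIDS[int(np.argmax(freq))])
    if not match_columns:
        raise ProfileError("profile has no match columns")

    return ProfileModel(
        columns=columns,
        background=background,
        consensus="".join(consensus_chars),
        ref_number_of_column=seed.reference_numbering(),
        pseudocount_weight=float(alpha),
        match_columns=match_columns,
    )


# ---------------------------------------------------------------------------
# Glocal alignment
# ---------------------------------------------------------------------------


@dataclass
class ProfileAlignment:
    """Result of aligning one query glocally to a profile.

    ``path`` holds ``(query_position, profile_column)`` pairs for aligned
    residues; query positions are 1-based, profile columns are 0-based
    indices into ``ProfileModel.columns`` (match columns only), and the path
    is strictly increasing in both coordinates.
    """

    query_id: str
    score_bits: float
    path: list[tuple[int, int]]
    coverage: float
    flank_lengths: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "score_bits": self.score_bits,
            "path": [list(p) for p in self.path],
            "coverage": self.coverage,
            "flank_lengths": list(self.flank_lengths),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileAlignment":
        return cls(
            query_id=d["query_id"],
            score_bits=float(d["score_bits"]),
            path=[tuple(p) for p in d["path"]],
            coverage=float(d["coverage"]),
            flank_lengths=tuple(d["flank_lengths"]),
        )


def encode_query(query: str) -> np.ndarray:
    """Encode a protein string to integer indices; ``X`` -> -1."""
    if not query:
        raise ProfileError("query is empty")
    idx = np.empty(len(query), dtype=np.int64)
    for i, ch in enumerate(query):
        if ch == AMBIGUOUS:
            idx[i] = -1
        else:
            j = AA_INDEX.get(ch)
            if j is None:
                raise ProfileError(f"query contains invalid residue {ch!r}")
            idx[i] = j
    return idx


def _gap_run_cost(length: int, gap_open: float, gap_extend: float) -> float:
    """Cost of a gap run: open for the first position, extend for the rest."""
    if length <= 0:
        return 0.0
    return gap_open + (length - 1) * gap_extend


def _score_matrix(query_idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """(n, m) residue-vs-match-column scores; ambiguous residues score 0."""
    n = query_idx.shape[0]
    m = log_odds.shape[0]
    S = np.zeros((n, m))
    known = query_idx >= 0
    S[known, :] = log_odds[:, query_idx[known]].T
    return S


def _glocal_dp(S: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three-state glocal DP matrices.

    States, indexed ``[i, j]`` with i consumed query residues (0..n) and j
    processed profile columns (0..m):

    - ``M``: residue i aligned to column j (includes a fresh start with
      leading profile deletions charged and leading query residues free);
    - ``D``: column j deleted between two aligned pairs;
    - ``I``: residue i inserted after column j between two aligned pairs.

    Leading/trailing query overhangs are free; leading/trailing profile
    deletions are charged as ordinary gap runs (glocal regime).
    """
    n, m = S.shape
    NEG = -np.inf
    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)
    I = np.full((n + 1, m + 1), NEG)
    ii = np.arange(n + 1)
    for j in range(1, m + 1):
        start_j = -_gap_run_cost(j - 1, gap_open, gap_extend)
        prev_best = np.maximum(np.maximum(M[:n, j - 1], D[:n, j - 1]), I[:n, j - 1])
        M[1:, j] = S[:, j - 1] + np.maximum(prev_best, start_j)
        D[:, j] = np.maximum(
            np.maximum(M[:, j - 1], I[:, j - 1]) - gap_open, D[:, j - 1] - gap_extend
        )
        # I[i, j] = max over i' < i of max(M[i',j], D[i',j]) - open - (i-1-i')*extend
        B = np.maximum(M[:, j], D[:, j]) - gap_open + ii * gap_extend
        run = np.maximum.accumulate(B)
        I[1:, j] = run[:n] - ii[1:] * gap_extend + gap_extend
        # note: I[i] = runmax(B[0..i-1]) - (i-1)*extend
    return M, D, I


def align_to_profile(
    query: str,
    profile: ProfileModel,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
) -> ProfileAlignment:
    """Glocal-align a query to the profile's match columns.

    Returns the maximum-scoring alignment; ties in traceback are broken
    deterministically as match > deletion > insertion, and among end cells
    the largest profile column then the largest query position wins.
    """
    query_idx = encode_query(query)
    log_odds = profile.match_log_odds()
    S = _score_matrix(query_idx, log_odds)
    n, m = S.shape
    M, D, I = _glocal_dp(S, gap_open, gap_extend)

    # best end: M[i, j] minus the cost of deleting trailing columns j+1..m
    end_cost = np.array([_gap_run_cost(m - j, gap_open, gap_extend) for j in range(m + 1)])
    total = M - end_cost[None, :]
    empty_score = -_gap_run_cost(m, gap_open, gap_extend)
    best = np.max(total[:, 1:]) if m else -np.inf
    if not np.isfinite(best) or best < empty_score:
        return ProfileAlignment(query_id, float(empty_score), [], 0.0, (n, 0))

    eps = 1e-9
    # tie-break: largest j, then largest i
    best_i = best_j = None
    for j in range(m, 0, -1):
        col = total[:, j]
        cand = np.nonzero(col >= best - eps)[0]
        if cand.size:
            best_i, best_j = int(cand[-1]), j
            break
    assert best_i is not None

    # traceback
    path_rev: list[tuple[int, int]] = []
    state, i, j = "M", best_i, best_j
    while True:
        if state == "M":
            path_rev.append((i, j))
            target = M[i, j] - S[i - 1, j - 1]
            start_j = -_gap_run_cost(j - 1, gap_open, gap_extend)
            if abs(M[i - 1, j - 1] - target) < eps:
                state, i, j = "M", i - 1, j - 1
            elif abs(D[i - 1, j - 1] - target) < eps:
                state, i, j = "D", i - 1, j - 1
            elif abs(I[i - 1, j - 1] - target) < eps:
                state, i, j = "I", i - 1, j - 1
            elif abs(start_j - target) < eps:
                break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed in M state")
        elif state == "D":
            target = D[i, j]
            if abs(M[i, j - 1] - gap_open - target) < eps:
                state, j = "M", j - 1
            elif abs(D[i, j - 1] - gap_extend - target) < eps:
                state, j = "D", j - 1
            elif abs(I[i, j - 1] - gap_open - target) < eps:
                state, j = "I", j - 1
            else:  # pragma: no cover
                raise AssertionError("traceback failed in D state")
        else:  # state == "I"
            target = I[i, j]
            if abs(M[i - 1, j] - gap_open - target) < eps:
                state, i = "M", i - 1
            elif abs(D[i - 1, j] - gap_open - target) < eps:
                state, i = "D", i - 1
            elif abs(I[i - 1, j] - gap_extend - target) < eps:
                state, i = "I", i - 1
            else:  # pragma: no cover
                raise AssertionError("traceback failed in I state")

    path_match = path_rev[::-1]  # (query_pos, 1-based match-column ordinal)
    path = [(qi, profile.match_columns[jj - 1]) for qi, jj in path_match]
    coverage = len(path) / m
    first_q = path_match[0][0]
    last_q = path_match[-1][0]
    return ProfileAlignment(
        query_id=query_id,
        score_bits=float(best),
        path=path,
        coverage=float(coverage),
        flank_lengths=(first_q - 1, n - last_q),
    )


def residues_at_refs(alignment: ProfileAlignment, profile: ProfileModel, query: str) -> dict[int, str]:
    """Map reference residue numbers -> query residues along an alignment."""
    out: dict[int, str] = {}
    for qpos, col in alignment.path:
        ref = profile.ref_number_of_column.get(col)
        if ref is not None:
            out[ref] = query[qpos - 1]
    return out


# ---------------------------------------------------------------------------
# Empirical E-value calibration
# ---------------------------------------------------------------------------


@dataclass
class EvalueCalibration:
    """Empirical score -> E-value map from shuffled-decoy scores.

    ``E(s) = N * P(S >= s)`` with ``P`` taken from the empirical decoy
    survival function below the top decile and an exponential tail fitted to
    the exceedances above it, so extreme scores extrapolate smoothly.
    """

    n_decoys: int
    decoy_scores: np.ndarray  # sorted ascending
    tail_fit: tuple[float, float]  # (location, scale)
    database_size: int
    seed: int | None = None

    def evalue(self, score) -> np.ndarray | float:
        s = np.asarray(score, dtype=float)
        loc, scale = self.tail_fit
        tail_frac = float(np.sum(self.decoy_scores >= loc)) / self.n_decoys
        emp = (self.n_decoys - np.searchsorted(self.decoy_scores, s, side="left")) / self.n_decoys
        tail = tail_frac * np.exp(-(s - loc) / scale)
        p = np.where(s > loc, np.minimum(tail, tail_frac), emp)
        out = self.database_size * np.minimum(p, 1.0)
        return float(out) if np.isscalar(score) else out


def calibrate_evalues(
    profile: ProfileModel,
    targets: list[str],
    n_shuffles: int = 500,
    seed: int = 0,
    database_size: int | None = None,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
    tail_quantile: float = 0.9,
) -> EvalueCalibration:
    """Score residue-shuffles of randomly chosen targets to calibrate E-values."""
    if n_shuffles < 100:
        raise ProfileError("need at least 100 shuffled decoys")
    if not targets:
        raise ProfileError("no target sequences to shuffle")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        t = targets[int(rng.integers(len(targets)))]
        chars = np.array(list(t))
        rng.shuffle(chars)
        decoy = "".join(chars)
        scores[k] = align_to_profile(decoy, profile, gap_open, gap_extend).score_bits
    scores.sort()
    cut = int(np.floor(tail_quantile * n_shuffles))
    loc = float(scores[cut])
    exceed = scores[cut:] - loc
    if exceed.size < 10:
        raise ProfileError("fewer than 10 decoy scores in the tail-fit region")
    scale = max(float(np.mean(exceed)), 1e-9)
    return EvalueCalibration(
        n_decoys=n_shuffles,
        decoy_scores=scores,
        tail_fit=(loc, scale),
        database_size=database_size if database_size is not None else len(targets),
        seed=seed,
    )
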