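"""Inverted-duplication detection by self-versus-reverse-complement comparison.

The detector finds pairs of intervals on one reference where one copy matches
the reverse complement of the other (an inverted segmental duplication, such
as the IL28A/IL28B pair on chromosome 19). Strategy: exact k-mer seeds
between the sequence and its reverse complement, diagonal clustering,
ungapped X-drop extension to the block boundaries, then an affine-gap global
alignment of the two copies to obtain percent identity and a per-base
coordinate map.

Percent identity is defined as matches / alignment columns, with gap columns
counted in the denominator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .seqio import NucleotideSequence, reverse_complement

NEG_INF = float("-inf")

# traceback state codes
_M, _X, _Y = 0, 1, 2


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring: a gap of length L costs gap_open + L * gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("scoring requires match > mismatch")


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("column with a gap in both rows")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.matches / self.columns

    def match_mask(self) -> np.ndarray:
        a = np.frombuffer(self.aligned_a.encode(), dtype="S1")
        b = np.frombuffer(self.aligned_b.encode(), dtype="S1")
        return (a == b) & (a != b"-")


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on the forward strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class DuplicationBlock:
    """An aligned pair of intervals on one reference, one copy per strand.

    `alignment.aligned_a` is the forward-strand copy_a slice; `aligned_b` is
    the copy_b slice read in its pairing orientation (reverse-complemented
    for inverted blocks), so the two rows are directly comparable.
    """

    copy_a: Interval
    copy_b: Interval
    orientation: str  # "inverted" | "direct"
    identity_percent: float
    alignment: PairwiseAlignment
    block_id: str = "block"

    def host_copy(self, position: int) -> str | None:
        """Which copy ('a'/'b') contains a 1-based position, if any."""
        if self.copy_a.contains(position):
            return "a"
        if self.copy_b.contains(position):
            return "b"
        return None


@dataclass
class CoordinateMap:
    """Per-base correspondence between the two copies of a block.

    `columns[k] = (pos_a | None, pos_b | None)` gives the forward-strand
    1-based positions consumed in alignment column k (None marks a gap).
    Restricted to gap-free columns the mapping is a bijection; for an
    inverted block mapped copy_b positions strictly decrease as copy_a
    positions increase.
    """

    block: DuplicationBlock
    columns: list[tuple[int | None, int | None]]
    a_to_b: dict[int, int | None]
    b_to_a: dict[int, int | None]

    def position_to_column(self, copy: str) -> dict[int, int]:
        """Cached map: forward-strand position on a copy -> column index."""
        attr = "_a_cols" if copy == "a" else "_b_cols"
        cached = getattr(self, attr, None)
        if cached is None:
            idx = 0 if copy == "a" else 1
            cached = {
                pair[idx]: k
                for k, pair in enumerate(self.columns)
                if pair[idx] is not None
            }
            object.__setattr__(self, attr, cached)
        return cached

    def column_of(self, position: int, copy: str) -> int:
        """Alignment column index (0-based) consuming a given position."""
        try:
            return self.position_to_column(copy)[position]
        except KeyError:
            raise KeyError(
                f"position {position} not in copy_{copy} of {self.block.block_id}"
            ) from None


def align_global(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    band: int | None = None,
) -> PairwiseAlignment:
    """Optimal affine-gap global (Needleman–Wunsch/Gotoh) alignment.

    Deterministic tie-break in the traceback: diagonal over up (gap in b)
    over left (gap in a). With `band`, cells farther than `band` columns
    from the length-proportional diagonal are excluded (the optimum is then
    banded-optimal; callers use this for long, near-colinear copies).
    """
    if scoring is None:
        scoring = Scoring()
    if not a or not b:
        raise ValueError("align_global requires non-empty sequences")
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend

    a_arr = np.frombuffer(a.encode(), dtype="S1")
    b_arr = np.frombuffer(b.encode(), dtype="S1")

    ptr_m = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.uint8)

    js = np.arange(m + 1, dtype=float)
    prev_m = np.full(m + 1, NEG_INF)
    prev_x = np.full(m + 1, NEG_INF)
    prev_y = np.full(m + 1, NEG_INF)
    prev_m[0] = 0.0
    if m >= 1:
        prev_y[1:] = go + ge * js[1:]
        ptr_y[0, 1] = _M
        ptr_y[0, 2:] = _Y

    for i in range(1, n + 1):
        cur_m = np.full(m + 1, NEG_INF)
        cur_x = np.empty(m + 1)
        cur_y = np.full(m + 1, NEG_INF)

        # X (up move, gap in b): predecessors from row i-1, same column
        cand_m = prev_m + go
        cand_y = prev_y + go
        best = cand_m.copy()
        ptr = np.zeros(m + 1, dtype=np.uint8)
        better = prev_x > best
        best[better] = prev_x[better]
        ptr[better] = _X
        better = cand_y > best
        best[better] = cand_y[better]
        ptr[better] = _Y
        cur_x = best + ge
        ptr_x[i, :] = ptr

        # M (diagonal): predecessors at (i-1, j-1)
        if m >= 1:
            sub = np.where(a_arr[i - 1] == b_arr, scoring.match, scoring.mismatch)
            best = prev_m[:-1].copy()
            ptr = np.zeros(m, dtype=np.uint8)
            better = prev_x[:-1] > best
            best[better] = prev_x[:-1][better]
            ptr[better] = _X
            better = prev_y[:-1] > best
            best[better] = prev_y[:-1][better]
            ptr[better] = _Y
            cur_m[1:] = best + sub
            ptr_m[i, 1:] = ptr

        if band is not None:
            center = i * m / n
            lo = int(np.floor(center - band))
            hi = int(np.ceil(center + band))
            mask = (js < lo) | (js > hi)
            mask[0] = mask[0] and i > 0  # keep column 0 reachable only via X
            cur_m[mask] = NEG_INF
            cur_x[mask & (js > hi)] = NEG_INF

        # Y (left move, gap in a): within-row prefix-max recurrence
        if m >= 1:
            u = np.maximum(cur_m + go, cur_x + go)
            u_ptr = np.where(cur_m + go >= cur_x + go, _M, _X).astype(np.uint8)
            t = u - ge * js
            run = np.maximum.accumulate(t)
            cur_y[1:] = run[:-1] + ge * js[1:]
            # predecessor: fresh open at j-1 beats an extended gap on ties
            fresh = t[:-1] >= np.concatenate(([NEG_INF], run[:-2])) if m >= 2 else np.array([True])
            ptr_row = np.where(fresh, u_ptr[:-1], _Y).astype(np.uint8)
            ptr_y[i, 1:] = ptr_row
            if band is not None:
                cur_y[mask] = NEG_INF

        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y

    finals = (prev_m[m], prev_x[m], prev_y[m])
    state = int(np.argmax(finals))  # argmax returns first max: prefers M > X > Y
    score = finals[state]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = int(ptr_m[i, j])
            i -= 1
            j -= 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = int(ptr_x[i, j])
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = int(ptr_y[i, j])
            j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score))


def identity_profile(
    alignment: PairwiseAlignment, window: int
) -> list[tuple[int, float]]:
    """Sliding-window identity over alignment columns (step 1).

    Returns (1-based window start column, percent identity) per position;
    gap columns count as non-matches.
    """
    cols = alignment.columns
    if window < 1 or window > cols:
        raise ValueError(f"window {window} outside [1, {cols}]")
    mask = alignment.match_mask().astype(int)
    csum = np.concatenate(([0], np.cumsum(mask)))
    out = []
    for start in range(cols - window + 1):
        matches = csum[start + window] - csum[start]
        out.append((start + 1, 100.0 * matches / window))
    return out


def build_coordinate_map(block: DuplicationBlock) -> CoordinateMap:
    """Per-base map between copy_a and copy_b positions via the block alignment.

    For inverted blocks, copy_b is consumed from its high end downward
    (aligned_b is the reverse complement of the copy_b forward-strand slice).
    """
    aln = block.alignment
    inverted = block.orientation == "inverted"
    pa = block.copy_a.start
    pb = block.copy_b.end if inverted else block.copy_b.start
    step_b = -1 if inverted else 1
    columns: list[tuple[int | None, int | None]] = []
    a_to_b: dict[int, int | None] = {}
    b_to_a: dict[int, int | None] = {}
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        pos_a = pos_b = None
        if ca != "-":
            pos_a = pa
            pa += 1
        if cb != "-":
            pos_b = pb
            pb += step_b
        columns.append((pos_a, pos_b))
        if pos_a is not None:
            a_to_b[pos_a] = pos_b
        if pos_b is not None:
            b_to_a[pos_b] = pos_a
    return CoordinateMap(block=block, columns=columns, a_to_b=a_to_b, b_to_a=b_to_a)


# ---------------------------------------------------------------------------
# seeded detection


def _seed_hits(s: str, r: str, k: int, max_kmer_hits: int = 16) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    hits = []
    for j in range(len(r) - k + 1):
        kmer = r[j : j + k]
        positions = index.get(kmer)
        if positions and len(positions) <= max_kmer_hits:
            for i in positions:
                hits.append((i, j))
    return hits


def _cluster_hits(
    hits: list[tuple[int, int]], k: int, band_tol: int = 25, max_seed_gap: int = 300
) -> list[dict]:
    clusters: list[dict] = []
    for i, j in sorted(hits, key=lambda h: (h[1] - h[0], h[0])):
        d = j - i
        placed = False
        for c in clusters:
            if abs(d - c["d"]) <= band_tol and -k <= i - c["i1"] <= max_seed_gap:
                c["i1"] = max(c["i1"], i)
                c["j0"] = min(c["j0"], j)
                c["j1"] = max(c["j1"], j)
                c["d"] = d
                c["n"] += 1
                placed = True
                break
        if not placed:
            clusters.append({"i0": i, "i1": i, "j0": j, "j1": j, "d": d, "n": 1})
    return clusters


def _xdrop_extend(
    s: str, r: str, i0: int, i1: int, j0: int, j1: int, xdrop: float = 25.0
) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of [i0,i1) vs [j0,j1) along the diagonal."""
    match, mismatch = 1.0, -3.0
    # leftward
    score = best = 0.0
    best_off = 0
    off = 0
    while i0 - off - 1 >= 0 and j0 - off - 1 >= 0:
        off += 1
        score += match if s[i0 - off] == r[j0 - off] else mismatch
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    i0 -= best_off
    j0 -= best_off
    # rightward
    score = best = 0.0
    best_off = 0
    off = 0
    while i1 + off < len(s) and j1 + off < len(r):
        score += match if s[i1 + off] == r[j1 + off] else mismatch
        off += 1
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    i1 += best_off
    j1 += best_off
    return i0, i1, j0, j1


def _score_alignment(aligned_a: str, aligned_b: str, scoring: Scoring) -> float:
    score = 0.0
    in_gap: str | None = None
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            score += scoring.match if x == y else scoring.mismatch
            in_gap = None
        else:
            which = "a" if x == "-" else "b"
            score += scoring.gap_extend + (scoring.gap_open if in_gap != which else 0.0)
            in_gap = which
    return score


def _trim_alignment_ends(
    aln: PairwiseAlignment, scoring: Scoring | None = None
) -> tuple[PairwiseAlignment, int, int, int, int] | None:
    """Trim both alignment ends to the maximum-scoring column segment.

    Seed extension can overrun a block's true boundary into unrelated
    sequence; those overhang columns score negatively (about 25% identity)
    and are removed here without touching the block interior. Returns the
    trimmed alignment plus the number of copy_a/copy_b bases dropped on the
    left and right, or None when nothing scores positive.
    """
    scoring = scoring or Scoring()
    col_scores = np.where(aln.match_mask(), 1.0, -2.0)
    csum = np.concatenate(([0.0], np.cumsum(col_scores)))
    k1 = int(np.argmax(csum))
    k0 = int(np.argmin(csum[: k1 + 1]))
    if k1 <= k0:
        return None
    a_rows = aln.aligned_a
    b_rows = aln.aligned_b
    trimmed = PairwiseAlignment(
        a_rows[k0:k1], b_rows[k0:k1],
        score=_score_alignment(a_rows[k0:k1], b_rows[k0:k1], scoring),
    )
    a_left = sum(1 for ch in a_rows[:k0] if ch != "-")
    a_right = sum(1 for ch in a_rows[k1:] if ch != "-")
    b_left = sum(1 for ch in b_rows[:k0] if ch != "-")
    b_right = sum(1 for ch in b_rows[k1:] if ch != "-")
    return trimmed, a_left, a_right, b_left, b_right


def _trim_to_identity(
    aln: PairwiseAlignment,
    min_identity_percent: float,
    min_columns: int,
    scoring: Scoring | None = None,
) -> tuple[PairwiseAlignment, int, int, int, int] | None:
    """Shave end mismatch runs until the alignment meets an identity floor.

    A block whose interior satisfies the identity threshold can be dragged
    just below it by a few matched-by-luck overhang columns at the ends;
    this removes, from whichever end costs fewer columns, up to and
    including the nearest mismatch column, repeating until the identity
    floor is met or the alignment would fall under `min_columns` (then
    None). Interior columns are never touched.
    """
    scoring = scoring or Scoring()
    mask = aln.match_mask()
    cols = len(mask)
    mism = np.nonzero(~mask)[0]
    left, right = 0, cols  # half-open window
    matches = int(mask.sum())
    lo_idx, hi_idx = 0, len(mism) - 1
    thr = min_identity_percent / 100.0
    while right - left >= min_columns and matches < thr * (right - left):
        if lo_idx > hi_idx:
            break  # no mismatches left yet identity below floor: impossible
        l_cost = mism[lo_idx] - left + 1
        r_cost = right - mism[hi_idx]
        if l_cost <= r_cost:
            matches -= int(mask[left : left + l_cost].sum())
            left += int(l_cost)
            lo_idx += 1
        else:
            matches -= int(mask[right - r_cost : right].sum())
            right -= int(r_cost)
            hi_idx -= 1
    if right - left < min_columns or matches < thr * (right - left):
        return None
    a_rows, b_rows = aln.aligned_a, aln.aligned_b
    trimmed = PairwiseAlignment(
        a_rows[left:right], b_rows[left:right],
        score=_score_alignment(a_rows[left:right], b_rows[left:right], scoring),
    )
    a_left = sum(1 for ch in a_rows[:left] if ch != "-")
    a_right = sum(1 for ch in a_rows[right:] if ch != "-")
    b_left = sum(1 for ch in b_rows[:left] if ch != "-")
    b_right = sum(1 for ch in b_rows[right:] if ch != "-")
    return trimmed, a_left, a_right, b_left, b_right


def find_inverted_duplications(
    seq: NucleotideSequence,
    seed_k: int = 15,
    min_block_length: int = 300,
    min_identity_percent: float = 90.0,
    merge_gap: int = 100,
    scoring: Scoring | None = None,
) -> list[DuplicationBlock]:
    """Detect inverted duplication blocks within one sequence.

    Compares the sequence to its own reverse complement. Fold-back
    (palindromic) self-matches whose two projected intervals overlap by
    more than half of the shorter one are discarded, and each physical
    duplication is reported once, canonically with copy_a upstream of
    copy_b. Blocks separated by short low-identity gaps (< `merge_gap` bp
    on both copies) are merged and re-aligned. Returned blocks are sorted
    by copy_a start.
    """
    s = seq.residues
    L = len(s)
    if L < 2 * min_block_length:
        raise ValueError("sequence shorter than twice min_block_length")
    r = reverse_complement(s)
    hits = _seed_hits(s, r, seed_k)
    clusters = _cluster_hits(hits, seed_k)

    candidates: list[tuple[int, int, int, int]] = []
    for c in clusters:
        i0, i1 = c["i0"], c["i1"] + seed_k
        j0, j1 = c["j0"], c["j1"] + seed_k
        if i1 - i0 < seed_k * 2 and c["n"] < 2:
            continue
        i0, i1, j0, j1 = _xdrop_extend(s, r, i0, i1, j0, j1)
        candidates.append((i0, i1, j0, j1))

    # project to forward-strand intervals, canonicalize, palindrome-filter
    raw: list[tuple[Interval, Interval]] = []
    for i0, i1, j0, j1 in candidates:
        copy_a = Interval(i0 + 1, i1)
        copy_b = Interval(L - j1 + 1, L - j0)
        if copy_a.start > copy_b.start:
            continue  # mirror representation of the same duplication
        shorter = min(copy_a.length, copy_b.length)
        if copy_a.overlap(copy_b) > 0.5 * shorter:
            continue  # fold-back palindrome
        raw.append((copy_a, copy_b))

    # merge blocks separated by a short gap on both copies
    raw.sort(key=lambda pair: pair[0].start)
    merged: list[tuple[Interval, Interval]] = []
    for copy_a, copy_b in raw:
        if merged:
            pa, pb = merged[-1]
            gap_a = copy_a.start - pa.end - 1
            gap_b = pb.start - copy_b.end - 1  # copy_b runs downstream→upstream
            if -seed_k <= gap_a < merge_gap and -seed_k <= gap_b < merge_gap:
                merged[-1] = (
                    Interval(pa.start, max(pa.end, copy_a.end)),
                    Interval(min(copy_b.start, pb.start), pb.end),
                )
                continue
        merged.append((copy_a, copy_b))

    blocks: list[DuplicationBlock] = []
    for copy_a, copy_b in merged:
        if copy_a.length < min_block_length or copy_b.length < min_block_length:
            continue
        sub_a = s[copy_a.start - 1 : copy_a.end]
        sub_b_rc = reverse_complement(s[copy_b.start - 1 : copy_b.end])
        band = None
        if max(len(sub_a), len(sub_b_rc)) > 1500:
            band = max(50, abs(len(sub_a) - len(sub_b_rc)) + 50)
        aln = align_global(sub_a, sub_b_rc, scoring=scoring, band=band)
        trim = _trim_alignment_ends(aln, scoring)
        if trim is None:
            continue
        aln, a_left, a_right, b_left, b_right = trim
        copy_a = Interval(copy_a.start + a_left, copy_a.end - a_right)
        # aligned_b runs antiparallel to copy_b: left trim drops high coords
        copy_b = Interval(copy_b.start + b_right, copy_b.end - b_left)
        if copy_a.length < min_block_length or copy_b.length < min_block_length:
            continue
        if aln.identity_percent < min_identity_percent:
            refined = _trim_to_identity(
                aln, min_identity_percent, min_block_length, scoring
            )
            if refined is None:
                continue
            aln, a_left, a_right, b_left, b_right = refined
            copy_a = Interval(copy_a.start + a_left, copy_a.end - a_right)
            copy_b = Interval(copy_b.start + b_right, copy_b.end - b_left)
            if copy_a.length < min_block_length or copy_b.length < min_block_length:
                continue
        blocks.append(
            DuplicationBlock(
                copy_a=copy_a,
                copy_b=copy_b,
                orientation="inverted",
                identity_percent=aln.identity_percent,
                alignment=aln,
            )
        )

    # drop redundant reports of the same duplication (>50% overlap on both copies)
    blocks.sort(key=lambda b: (-(b.copy_a.length), b.copy_a.start))
    kept: list[DuplicationBlock] = []
    for b in blocks:
        redundant = False
        for k_ in kept:
            ov_a = b.copy_a.overlap(k_.copy_a) / min(b.copy_a.length, k_.copy_a.length)
            ov_b = b.copy_b.overlap(k_.copy_b) / min(b.copy_b.length, k_.copy_b.length)
            if ov_a >= 0.5 and ov_b >= 0.5:
                redundant = True
                break
        if not redundant:
            kept.append(b)
    kept.sort(key=lambda b: b.copy_a.start)
    for idx, b in enumerate(kept, start=1):
        b.block_id = f"block_{idx}"
    return kept


# ---------------------------------------------------------------------------
# exports


def blocks_to_bed(blocks: list[DuplicationBlock], reference_id: str) -> str:
    """BED (0-based half-open): one line per copy; copy_b strand '-' when inverted."""
    lines = []
    for b in blocks:
        lines.append(
            f"{reference_id}\t{b.copy_a.start - 1}\t{b.copy_a.end}\t{b.block_id}_a\t"
            f"{b.identity_percent:.1f}\t+"
        )
        strand = "-" if b.orientation == "inverted" else "+"
        lines.append(
            f"{reference_id}\t{b.copy_b.start - 1}\t{b.copy_b.end}\t{b.block_id}_b\t"
            f"{b.identity_percent:.1f}\t{strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def blocks_to_tsv(blocks: list[DuplicationBlock]) -> str:
    header = (
        "block_id\tcopy_a_start\tcopy_a_end\tcopy_b_start\tcopy_b_end\t"
        "orientation\tlength_a\tlength_b\tidentity_percent\n"
    )
    buf = io.StringIO()
    buf.write(header)
    for b in blocks:
        buf.write(
            f"{b.block_id}\t{b.copy_a.start}\t{b.copy_a.end}\t{b.copy_b.start}\t"
            f"{b.copy_b.end}\t{b.orientation}\t{b.copy_a.length}\t{b.copy_b.length}\t"
            f"{b.identity_percent:.2f}\n"
        )
    return buf.getvalue()


def alignment_to_fasta(block: DuplicationBlock, reference_id: str) -> str:
    """Aligned-FASTA of the two copies (copy_b in pairing orientation)."""
    b = block
    return (
        f">{reference_id}_{b.block_id}_a/{b.copy_a.start}-{b.copy_a.end}\n"
        f"{b.alignment.aligned_a}\n"
        f">{reference_id}_{b.block_id}_b/{b.copy_b.start}-{b.copy_b.end}_rc\n"
        f"{b.alignment.aligned_b}\n"
    )
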