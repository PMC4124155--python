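"""PolII/PolIII promoter-element detection with position weight matrices.

snRNA-type genes transcribed by PolII or PolIII carry essential promoter
elements at stereotyped positions upstream of the transcript start: for
PolIII type-3 promoters a proximal sequence element (PSE, around -55)
plus a TATA box close to the transcript start; for PolII the proximal
sequence elements PSEA (-50) and PSEB (-25).  Candidate loci are scored
with log-odds PWMs over a 100-nt upstream slice, and pass when every
required element scores at or above an empirical threshold calibrated on
random background sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
SLICE_LEN = 100
DEFAULT_SLACK = 10
DEFAULT_ALPHA = 0.01
#: canonical anchors: distance of the element start upstream of the
#: transcript start (nt)
POLII_ANCHORS = {"PSEA": 50, "PSEB": 25}
POLIII_ANCHORS = {"PSE": 55, "TATA": 20}


@dataclass
class PWM:
    """Log-odds position weight matrix with an upstream anchor.

    ``weights`` is a (4, width) array over A,C,G,T in log2 odds against a
    uniform 0.25 background.  ``anchor_offset`` is the expected distance
    of the element's start upstream of the transcript start;
    ``window_slack`` widens the scan window by +/- that many nt.
    """

    element: str
    weights: np.ndarray
    anchor_offset: int | None = None
    window_slack: int = DEFAULT_SLACK

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("weights must have shape (4, width)")
        if self.weights.shape[1] < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite (use a pseudocount)")

    @property
    def width(self) -> int:
        return self.weights.shape[1]


@dataclass
class PromoterCall:
    locus_id: str
    mode: str  # polII | polIII
    element_scores: dict[str, tuple[float, int]] = field(default_factory=dict)
    passed: bool = False


def build_pwm(
    element: str,
    training_slices: list[str],
    pseudocount: float = 0.5,
    anchor_offset: int | None = None,
    window_slack: int = DEFAULT_SLACK,
) -> PWM:
    """Build a log2-odds PWM from aligned equal-length training sequences.

    weight[b, j] = log2((count[b, j] + pseudocount) /
    (n + 4 * pseudocount) / 0.25).
    """
    if len(training_slices) < 2:
        raise ValueError("need at least 2 training slices")
    width = len(training_slices[0])
    if width == 0:
        raise ValueError("PWM width must be >= 1")
    if any(len(s) != width for s in training_slices):
        raise ValueError("training slices must have equal length")
    counts = np.zeros((4, width))
    for s in training_slices:
        for j, c in enumerate(s.upper()):
            if c not in _INDEX:
                raise ValueError(f"training slices must be over ACGT, got {c!r}")
            counts[_INDEX[c], j] += 1
    n = len(training_slices)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    return PWM(element, np.log2(freqs / 0.25), anchor_offset, window_slack)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    window: tuple[int, int] | None = None,
) -> tuple[float, int]:
    """Best summed log-odds score over allowed offsets; ties to smallest.

    ``window`` restricts the scanned start offsets to [lo, hi] inclusive;
    positions holding N contribute the minimum weight of their column (a
    conservative convention).
    """
    seq = sequence.upper()
    if len(seq) < pwm.width:
        raise ValueError("sequence shorter than PWM width")
    lo, hi = 0, len(seq) - pwm.width
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
        if lo > hi:
            raise ValueError(f"empty scan window {window}")
    col_min = pwm.weights.min(axis=0)
    best_score, best_off = -np.inf, lo
    for off in range(lo, hi + 1):
        score = 0.0
        for j in range(pwm.width):
            c = seq[off + j]
            score += pwm.weights[_INDEX[c], j] if c in _INDEX else col_min[j]
        if score > best_score:
            best_score, best_off = score, off
    return best_score, best_off


def anchor_window(pwm: PWM, slice_len: int = SLICE_LEN) -> tuple[int, int] | None:
    """Scan window (start offsets into the upstream slice) for an anchored PWM.

    The upstream slice runs from -slice_len to the transcript start, so an
    element starting ``anchor_offset`` nt upstream sits at slice offset
    slice_len - anchor_offset; the window widens by +/- window_slack.
    """
    if pwm.anchor_offset is None:
        return None
    center = slice_len - pwm.anchor_offset
    return (
        max(0, center - pwm.window_slack),
        min(slice_len - pwm.width, center + pwm.window_slack),
    )


def uniform_background_sampler(rng: np.random.Generator, length: int = SLICE_LEN):
    """Sampler of i.i.d. uniform ACGT sequences."""

    def sample() -> str:
        return "".join(rng.choice(list(ALPHABET), size=length))

    return sample


def genome_dinucleotide_sampler(
    genome, rng: np.random.Generator, length: int = SLICE_LEN
):
    """Sampler drawing sequences from a first-order (dinucleotide) chain
    estimated on the genome's non-N sequence."""
    counts = np.ones((4, 4))
    start = np.ones(4)
    for seq in genome.contigs.values():
        for a, b in zip(seq, seq[1:]):
            if a in _INDEX and b in _INDEX:
                counts[_INDEX[a], _INDEX[b]] += 1
                start[_INDEX[a]] += 1
    trans = counts / counts.sum(axis=1, keepdims=True)
    start = start / start.sum()

    def sample() -> str:
        out = [int(rng.choice(4, p=start))]
        for _ in range(length - 1):
            out.append(int(rng.choice(4, p=trans[out[-1]])))
        return "".join(ALPHABET[i] for i in out)

    return sample


def score_threshold(
    pwm: PWM,
    sampler,
    n: int = 1000,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    slice_len: int = SLICE_LEN,
) -> float:
    """Empirical (1 - alpha) quantile of best scan scores on background.

    ``sampler`` is either a zero-argument callable returning sequences or
    None, in which case a uniform sampler seeded with ``seed`` is used.
    The scan respects the PWM's anchor window, matching how candidate
    slices will be scored.
    """
    if n < 100:
        raise ValueError("need at least 100 background sequences")
    if sampler is None:
        sampler = uniform_background_sampler(
            np.random.default_rng(seed), slice_len
        )
    window = anchor_window(pwm, slice_len)
    scores = np.array(
        [scan_pwm(sampler(), pwm, window)[0] for _ in range(n)]
    )
    # alpha = 0 means: threshold at the sample maximum
    k = min(n - 1, int(np.floor((1.0 - alpha) * n)))
    return float(np.sort(scores)[k])


def classify_promoter(
    upstream_slice: str,
    mode: str,
    pwms: dict[str, PWM],
    thresholds: dict[str, float],
    locus_id: str = "",
    allow_inverted_pse: bool = False,
) -> PromoterCall:
    """Score the required promoter elements on a 100-nt upstream slice.

    polIII requires PSE and TATA (the TATA window anchored near the 3'
    end of the slice, i.e. just upstream of the transcript start); polII
    requires PSEA and PSEB.  The call passes when every required element's
    best in-window score reaches its threshold.  With
    ``allow_inverted_pse`` a polII slice also passes when PSEA and PSEB
    pass with their windows swapped (the spatially inverted arrangement
    seen for U4atac).
    """
    if len(upstream_slice) != SLICE_LEN:
        raise ValueError(
            f"upstream slice must be exactly {SLICE_LEN} nt, got {len(upstream_slice)}"
        )
    if mode == "polIII":
        required = ("PSE", "TATA")
    elif mode == "polII":
        required = ("PSEA", "PSEB")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    missing = [e for e in required if e not in pwms or e not in thresholds]
    if missing:
        raise ValueError(f"missing PWM or threshold for {missing}")
    call = PromoterCall(locus_id, mode)
    ok = True
    for element in required:
        pwm = pwms[element]
        score, off = scan_pwm(upstream_slice, pwm, anchor_window(pwm))
        call.element_scores[element] = (score, off)
        if score < thresholds[element]:
            ok = False
    if not ok and mode == "polII" and allow_inverted_pse:
        swapped_ok = True
        for element, other in (("PSEA", "PSEB"), ("PSEB", "PSEA")):
            pwm = pwms[element]
            score, off = scan_pwm(
                upstream_slice, pwm, anchor_window(pwms[other])
            )
            call.element_scores[f"{element}(inverted)"] = (score, off)
            if score < thresholds[element]:
                swapped_ok = False
        ok = swapped_ok
    call.passed = ok
    return call


# ---------------------------------------------------------------------------
# Plain-text PWM format
# ---------------------------------------------------------------------------

def write_pwms(pwms: dict[str, PWM], path) -> None:
    """Header line (element, width, anchor_offset, slack) + 4 x width matrix."""
    with open(path, "w") as fh:
        for pwm in pwms.values():
            anchor = "." if pwm.anchor_offset is None else str(pwm.anchor_offset)
            fh.write(f">{pwm.element}\t{pwm.width}\t{anchor}\t{pwm.window_slack}\n")
            for i, base in enumerate(ALPHABET):
                row = "\t".join(f"{w:.6f}" for w in pwm.weights[i])
                fh.write(f"{base}\t{row}\n")


def read_pwms(path) -> dict[str, PWM]:
    pwms: dict[str, PWM] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected PWM header at line {i + 1}")
        element, width_s, anchor_s, slack_s = lines[i][1:].split("\t")
        width = int(width_s)
        rows = []
        for j, base in enumerate(ALPHABET):
            parts = lines[i + 1 + j].split("\t")
            if parts[0] != base or len(parts) != width + 1:
                raise ValueError(f"bad matrix row for {element}")
            rows.append([float(x) for x in parts[1:]])
        pwms[element] = PWM(
            element,
            np.array(rows),
            None if anchor_s == "." else int(anchor_s),
            int(slack_s),
        )
        i += 5
    return pwms
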