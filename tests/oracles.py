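"""Independent oracles: naive implementations kept separate from the
library code paths they check."""

import random
from itertools import permutations

from moclosim.digestion import StickyFragment, TypeIISEnzyme
from moclosim.sequence_io import revcomp


def brute_site_scan(seq: str, recognition: str, circular: bool):
    """O(n·m) scan of both strands: list of (strand, start) occurrences."""
    n, m = len(seq), len(recognition)
    doubled = seq + seq[: m - 1] if circular else seq
    rc = revcomp(recognition)
    hits = []
    for p in range(n if circular else n - m + 1):
        window = doubled[p : p + m]
        if window == recognition:
            hits.append(("+", p))
        if window == rc:
            hits.append(("-", p))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def count_circular_chainings(fragments) -> int:
    """Number of circular orderings (rotations identified by fixing the
    first fragment) in which every junction's fusion sites match."""
    if len(fragments) < 2:
        return 0
    count = 0
    k = len(fragments)
    for perm in permutations(range(1, k)):
        order = [0] + list(perm)
        if all(
            fragments[order[i]].right_fusion == fragments[order[(i + 1) % k]].left_fusion
            for i in range(k)
        ):
            count += 1
    return count


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_redigestible_fragments(fusions, enzyme: TypeIISEnzyme, rng: random.Random):
    """Acceptor-style fragments that keep their flanking enzyme sites, so the
    assembled circle re-digests at every fusion back into the same
    fragments. Each payload is::

        [spacer][revcomp(recognition)]  middle  [recognition][spacer]

    placing one outward cut at the left fusion and one at the right.
    """
    rec = enzyme.recognition
    frags = []
    n = len(fusions)
    for i in range(n):
        left, right = fusions[i], fusions[(i + 1) % n]
        while True:
            middle = random_dna(rng, rng.randint(15, 60))
            payload = (
                random_dna(rng, enzyme.spacer_top)
                + revcomp(rec)
                + middle
                + rec
                + random_dna(rng, enzyme.spacer_top)
            )
            probe = payload + right  # stray sites would break the re-digest
            if probe.count(rec) == 1 and probe.count(revcomp(rec)) == 1:
                break
        frags.append(StickyFragment(left, payload, right, source_id=f"frag{i}"))
    return frags
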