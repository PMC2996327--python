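"""Independent oracles used by several test modules."""

from math import comb


def exact_sector_distribution(mu: float, generations: int) -> dict[int, float]:
    """Exact sector-count distribution of the synchronous colony tree.

    Dynamic programming over (fragment-bearing cells, sectors founded) states,
    enumerating every per-generation loss count with binomial weights.  Only
    feasible for small generation counts, which is what makes it an
    independent check on the vectorized simulator.
    """
    states = {(1, 0): 1.0}  # (white cells, sectors) -> probability
    for _ in range(generations):
        nxt: dict[tuple[int, int], float] = {}
        for (w, s), prob in states.items():
            for losses in range(w + 1):
                weight = comb(w, losses) * mu**losses * (1 - mu) ** (w - losses)
                key = (2 * w - losses, s + losses)
                nxt[key] = nxt.get(key, 0.0) + prob * weight
        states = nxt
    dist: dict[int, float] = {}
    for (_, s), prob in states.items():
        dist[s] = dist.get(s, 0.0) + prob
    return dist
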