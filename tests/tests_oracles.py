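"""Independent brute-force oracles shared across test modules."""


def brute_force_contacts(a, b, box, cutoff):
    """O(N^2) triple-loop minimum-image pair count."""
    n = 0
    for pa in a:
        for pb in b:
            d2 = 0.0
            for dim in range(3):
                delta = pa[dim] - pb[dim]
                delta -= box[dim] * round(delta / box[dim])
                d2 += delta * delta
            if d2 < cutoff * cutoff:
                n += 1
    return n
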