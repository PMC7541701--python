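"""Independent brute-force implementations of the five randomness indices.

Deliberately written as plain counting loops with no shared code with
:mod:`morra.metrics`; they serve as oracles in equivalence tests.
"""

import math


def naive_redundancy(values, alphabet=(1, 2, 3, 4, 5)):
    n = len(values)
    h = 0.0
    for s in alphabet:
        c = sum(1 for v in values if v == s)
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return 100.0 * (1.0 - h / math.log2(len(alphabet)))


def naive_fpr(values, alphabet=(1, 2, 3, 4, 5)):
    num = 0.0
    for x in alphabet:
        for y in alphabet:
            c = sum(
                1
                for i in range(len(values) - 1)
                if values[i] == x and values[i + 1] == y
            )
            if c > 1:
                num += c * math.log2(c)
    den = 0.0
    for s in alphabet:
        c = sum(1 for v in values if v == s)
        if c > 1:
            den += c * math.log2(c)
    if den == 0:
        return None
    return num / den


def naive_nsq(values, alphabet=(1, 2, 3, 4, 5)):
    a = len(alphabet)
    missing = 0
    for x in alphabet:
        for y in alphabet:
            found = any(
                values[i] == x and values[i + 1] == y
                for i in range(len(values) - 1)
            )
            if not found:
                missing += 1
    return 100.0 * missing / (a * a - 1)


def naive_coupon(values, alphabet=(1, 2, 3, 4, 5)):
    lengths = []
    seen = set()
    count = 0
    for v in values:
        seen.add(v)
        count += 1
        if seen == set(alphabet):
            lengths.append(count)
            seen = set()
            count = 0
    if not lengths:
        return None
    return sum(lengths) / len(lengths)


def naive_repetition_gap(values):
    gaps = []
    for i in range(len(values)):
        for j in range(i - 1, -1, -1):
            if values[j] == values[i]:
                gaps.append(i - j)
                break
    if not gaps:
        return None
    return sum(gaps) / len(gaps)
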