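import re

import pytest

from enzner.annotator import RuleConfig, Sentence
from enzner.dictionary import build_hierarchy, load_mini_dictionary


@pytest.fixture(scope="session")
def entries():
    return load_mini_dictionary()


@pytest.fixture(scope="session")
def tree(entries):
    return build_hierarchy(entries)


@pytest.fixture(scope="session")
def cfg():
    # fixed timestamp so repeated annotation runs compare equal
    return RuleConfig(timestamp="2024-01-01T00:00:00Z")


def brute_force_direct(sentence: Sentence, tree):
    """Independent oracle: try every dictionary form at every position,
    then repeatedly keep the longest (leftmost on ties) candidate and
    discard everything it overlaps."""
    cands = []
    for form in sorted(tree.all_forms()):
        pat = re.compile(
            r"(?<![^\W_])(?<!-)"
            + re.escape(form).replace("\\ ", "\\s+")
            + r"(?![^\W_])(?!-)",
            re.IGNORECASE | re.UNICODE,
        )
        for m in pat.finditer(sentence.text):
            ec = tree.ec_index.get(form)
            ident = ec if ec else form.split()[-1]
            cands.append((m.start(), m.end(), ident))
    chosen = []
    remaining = sorted(set(cands))
    while remaining:
        best = min(remaining, key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
        chosen.append(best)
        remaining = [
            c for c in remaining if c[1] <= best[0] or c[0] >= best[1]
        ]
    return {
        (sentence.start_offset + s, e - s, ident) for s, e, ident in chosen
    }
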