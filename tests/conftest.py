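import numpy as np
import pytest

from plantlinc.io import Transcript


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_transcripts(rng, n, min_len=1, max_len=600, alphabet="ACGT", prefix="r"):
    """Uniform random sequences, optionally with ambiguous bases."""
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(alphabet), size=length))
        out.append(Transcript(id=f"{prefix}{i}", seq=seq))
    return out


def brute_force_longest_orf(seq: str):
    """Independent quadratic oracle: for every ATG, walk in-frame codons to
    the first stop; return (start, end, nt_length) of the longest ORF with
    ties broken by smallest start, or None."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in stops:
                length = j + 3 - i
                if best is None or length > best[2]:
                    best = (i, j + 3, length)
                break
            j += 3
    return best
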