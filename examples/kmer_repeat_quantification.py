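"""Identify H3K9me2-enriched 12-mers and quantify repeat abundance.

Builds toy IP/input read sets where a satellite-like repeat is
overrepresented in the IP, calls enriched 12-mers at threefold, and
measures their abundance in a whole-genome read set.
"""

import numpy as np

from tespread import kmers as km

rng = np.random.default_rng(1)
satellite = "AACATAGAATAT"  # a 12-bp repeat unit


def random_read(length=50):
    return "".join(rng.choice(list("ACGT"), length))


# a shared genomic background sampled by both libraries, with the
# satellite strongly overrepresented in the IP
background = [random_read() for _ in range(300)]
ip_reads = [satellite * 4 for _ in range(60)] + background[:240]
input_reads = [satellite * 4 for _ in range(5)] + background[:295]

ip = km.count_kmers(ip_reads)
inp = km.count_kmers(input_reads)
het = km.enriched_kmers(ip, inp, fold=3.0)
print(f"heterochromatic 12-mers called (>=3x IP/input): {len(het)}")

wgs = [satellite * 4 for _ in range(20)] + [random_read() for _ in range(480)]
abundance = km.repeat_abundance(wgs, het, normalizer=len(wgs))
print(f"repeat abundance in WGS reads: {abundance:.2f} hits per read")
print("counting is on canonical k-mers (strand-symmetric); abundance is")
print("the summed count of the enriched set per normalizing read.")
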