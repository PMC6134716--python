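"""Write the five Swarm-compatible output files for a tiny clustering.

Four amplicons form one chain OTU (a <- b <- c) and one singleton; the
script prints each output format and what its columns mean.
"""

import sys
from io import StringIO

from ampliswarm import AbundanceDialect, Amplicon, ClusteringConfig, run_clustering
from ampliswarm.output import _WRITERS

amps = [
    Amplicon("a", "AAAAAAAA", 10, 0),
    Amplicon("b", "AAAAAAAT", 5, 1),
    Amplicon("c", "AAAAAATT", 3, 2),
    Amplicon("z", "GGGGGGGG", 1, 3),
]
result = run_clustering(amps, ClusteringConfig(t=1))

notes = {
    "membership": "one OTU per line, seed first, labels carry abundances",
    "statistics": "amplicons, weight, seed, seed abundance, singletons, "
                  "max generation, radius",
    "seeds": "FASTA of seeds annotated with total OTU weight",
    "uclust": "S/H/C records; H shows percent identity to the parent",
    "internal": "links: parent, child, distance, OTU number, generation",
}
for kind, writer in _WRITERS.items():
    buf = StringIO()
    writer(result, buf, AbundanceDialect())
    print(f"--- {kind} ({notes[kind]})")
    sys.stdout.write(buf.getvalue())
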