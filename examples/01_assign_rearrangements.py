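"""Assign a handful of heavy-chain rearrangements against the toy catalog.

Builds three sequences by hand — an exact copy of subset T1's consensus
CDR3, a near-copy with small edits that still passes the standard criteria,
and a length-shifted variant that only the relaxed satellite criteria
accept — and prints the tier, subset and scores each one receives.
"""

from cllsls import Rearrangement, assign_all, load_catalog, toy_catalog_path

catalog = load_catalog(toy_catalog_path())
t1 = next(s for s in catalog if s.subset_id == "T1")
print(f"subset T1: consensus {t1.consensus_cdr3}, motif {t1.motif} at offset {t1.motif_offset}")

rearrangements = [
    # exact consensus copy -> standard match at identity 1.0
    Rearrangement("exact", "IGHV1-69*01", "IGHJ6*01", f"C{t1.consensus_cdr3}W", v_identity=1.0),
    # two non-motif substitutions -> still standard (identity 11/13)
    Rearrangement("near", "IGHV5-51*01", "IGHJ6*01", "CAADKGYYSYGMDAW", v_identity=0.99),
    # two residues longer, motif shifted by +2 -> satellite only
    Rearrangement("shifted", "IGHV1-69*01", "IGHJ6*01", f"CAR{t1.consensus_cdr3}W", v_identity=1.0),
    # unrelated sequence -> no match
    Rearrangement("none", "IGHV3-23*01", "IGHJ4*01", "CAKGSGSYFDYW", v_identity=1.0),
]

for a in assign_all(rearrangements, catalog):
    print(
        f"{a.sequence_key:45s} -> {a.match_type:9s} subset={a.subset_id or '-':3s} "
        f"identity={a.identity:.2f} similarity={a.similarity:.2f} "
        f"dlen={a.length_delta:+d} doffset={a.offset_delta:+d}"
    )

print(
    "\nA standard match requires the same clan, equal CDR3 length, the motif at the\n"
    "identical offset and >=50% identity / >=70% similarity to the consensus; the\n"
    "satellite tier tolerates length and offset shifts of up to 2 residues."
)
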