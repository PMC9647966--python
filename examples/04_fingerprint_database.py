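"""Build a cultivar fingerprint database and detect duplicate genotypes.

Fingerprints 50 synthetic cultivars (with two planted clone groups)
over a fixed panel, reports the duplicate groups, and round-trips one
sample through the plain-text barcode payload.
"""

import tempfile
from pathlib import Path

import snpanel as sp
from snpanel.fingerprint import (
    build_db, decode_barcode, duplicate_report, encode_barcode,
)

with tempfile.TemporaryDirectory() as tmp:
    plan = sp.SynthPlan(
        n_samples=50, n_markers=15, het_rate=0.39, missing_rate=0.03,
        duplicate_groups=(12, 11), seed=21,
    )
    fx = sp.generate(plan, Path(tmp))
    panel = [m["id"] for m in fx.manifest["markers"]]
    db = build_db(fx.matrix, panel)

print(f"samples: {db.matrix.n_samples}, panel: {len(db.panel)} markers")
print(f"distinct genotypes: {db.n_groups}")
print(f"fully distinguished cultivars: {db.n_distinguished}")

dup = duplicate_report(db)
print("duplicate groups (candidate synonyms):")
for _, row in dup.iterrows():
    members = row["members"].split(",")
    print(f"  {row['size']} cultivars share one genotype "
          f"({members[0]} ... {members[-1]})")

sample = db.matrix.samples[0]
payload = encode_barcode(db, sample)
print(f"\nbarcode payload for {sample}: {payload[:40]}...")
decoded_sample, calls = decode_barcode(payload, db)
assert decoded_sample == sample
print(f"decoded back {len(calls)} calls for {decoded_sample}")
print(f"genotype string: {db.entries[sample].joined}")
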