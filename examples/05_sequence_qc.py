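"""Run the sequence quality-control cascade on synthetic barcode data.

Builds a family-structured panel of coding sequences, plants one
mislabelled record (a verbatim copy of a sequence from another family) and
one frame-shifted record, and runs the full chain.  The report shows each
dropped record with the rule that fired.
"""

from chronopl.qc import Checklist, TaxonRecord, run_qc
from chronopl.simulate import simulate_sequences, simulate_taxonomy

taxonomy = simulate_taxonomy(15, n_genera=8, n_families=3, n_orders=2, seed=6)
records = simulate_sequences(taxonomy, seed=6)
fam_of = dict(zip(taxonomy["species"], taxonomy["family"]))

donor = next(r for r in records if fam_of[r.species_name] != fam_of[records[0].species_name])
bad = [
    TaxonRecord(records[0].species_name, "rbcL", "MISLAB01", donor.sequence),
    TaxonRecord(records[1].species_name, "rbcL", "SHIFT001",
                records[1].sequence[:40] + records[1].sequence[41:]),
]
checklist = Checklist.from_names("both", taxonomy["species"])
kept, report = run_qc(records + bad, records, fam_of, checklist, checklist)
print(f"kept {len(kept)} of {len(records) + len(bad)} records")
for entry in report.entries:
    if entry["verdict"] == "dropped":
        print(f"  dropped {entry['accession']:9s} rule={entry['rule']}")
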