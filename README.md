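# beaconkit

Federated genomic beacons — and a quantitative account of their privacy.

A *beacon* is a web-accessible service that answers one deliberately narrow
question about a genomic dataset: **"Have you observed this allele?"** — for
example, nucleotide C at position 32,936,732 on chromosome 13 — with a plain
"yes" or "no". Because nothing about any individual sample is returned,
beacons let hospitals, archives, and consortia make datasets *discoverable*
without shipping VCFs around, and many beacons can be federated into a network
that answers the complementary question, "*Who* has observed this allele?".

`beaconkit` is a complete, self-contained implementation of that protocol and
of the analyses needed to operate it responsibly:

- **Allele stores** (`beaconkit.allele_store`) — exact-match indexes built
  from VCF v4.x files (plain or bgzipped, via pysam): multi-allelic splitting,
  reference-free REF/ALT trimming, AC/AN or genotype-derived counts,
  0-based public coordinates.
- **The protocol engine** (`beaconkit.beacon_core`) — the two beacon
  functions, `info` and `query`, with OR-over-datasets semantics and a fixed
  JSON wire dialect (`GET /` and `GET /query`).
- **Access control** (`beaconkit.access_control`) — ordered
  open/registered/controlled tiers with *progressive disclosure* (each tier
  unlocks a superset of the fields below it), and Consent-Code purpose gating
  (NRES/GRU/HMB/DS-term/POA against the query's declared research purpose).
- **Information budgeting** (`beaconkit.privacy_budget`) — each answered query
  is priced in bits, `-log2 f` for a "yes" about an allele at frequency *f*
  (floored), a small constant for a "no"; a credential whose cumulative
  disclosure reaches the ledger threshold (default 30 bits) is locked out.
- **Federation** (`beaconkit.network`) — registries, concurrent fan-out with
  per-beacon fault isolation, and origin-obscuring *aggregate beacons* whose
  answer is the OR over hidden members.
- **Attack simulation** (`beaconkit.attack_sim`) — synthetic diploid
  populations with a known allele-frequency spectrum, and seeded Monte-Carlo
  membership-inference experiments measuring how re-identification power
  scales with query count, beacon size, and allele rarity, with and without
  the budget defense.

## The statistics at the core

An attacker holding a target's genotypes queries the beacon at sites where the
target carries the alternate allele and tests "target is a member" against
"target is not". For responses x_i ∈ {0,1} at population frequencies f_i, with
N diploid members and per-copy mismatch rate δ, the frequency-aware
log-likelihood-ratio statistic is

    Λ = Σ_i [ x_i · ln(P_in / P_out) + (1 − x_i) · ln((1 − P_in)/(1 − P_out)) ]

    P_out = 1 − (1 − f_i)^(2N)          (allele present among N non-members)
    P_in  = 1 − δ · (1 − f_i)^(2(N−1))  (present given the target is a member)

The frequency-agnostic statistic is simply the fraction of "yes" responses.
Decision thresholds are calibrated empirically — the (1−α) quantile of the
non-member statistic distribution — so the achieved false-positive rate is
≤ α by construction, and *power* is the fraction of member trials above the
threshold. The budget defense works because the same rare alleles that carry
the attacker's evidence are exactly the ones priced highest by `-log2 f`.

## Worked example

Light a beacon from a simulated 50-sample cohort and query it:

```
$ beaconkit fixtures write-vcf --n-individuals 100 --n-snps 500 --members 50 \
      --seed 7 --out cohort.vcf
{"samples": 50, "sites": 463, "vcf": "cohort.vcf"}
```

with a service config `beacon.json`:

```json
{
  "beacon_id": "demo-beacon",
  "organization": "Example Institute",
  "datasets": [
    {"path": "cohort.vcf", "dataset_id": "cohort", "assembly_id": "SYNTH",
     "consent": {"primary_category": "GRU"}, "minimum_tier": "OPEN"}
  ],
  "token_registry": {"r-42": "REGISTERED"},
  "budget": {"threshold_bits": 30.0}
}
```

An anonymous (open-tier) query discloses existence only — exit code 0 means
"yes":

```
$ beaconkit query --config beacon.json --assembly SYNTH \
      --chrom 1 --start 0 --ref A --alt C --include-datasets
{"beaconId": "demo-beacon", "exists": true,
 "datasetAlleleResponses": [{"datasetId": "cohort", "exists": true}]}
```

The same query with a registered-tier token additionally unlocks the allele
count and frequency (18 alt copies among 100 called alleles):

```
$ beaconkit query ... --token r-42
{"beaconId": "demo-beacon", "exists": true,
 "datasetAlleleResponses": [{"datasetId": "cohort", "exists": true,
                             "alleleCount": 18, "frequency": 0.18}]}
```

How dangerous is unlimited querying? Against a 100-member beacon, 5,000
yes-count queries re-identify members essentially always (power 1.0 at 2%
achieved FPR), while a 30-bit information budget cuts the attacker off after
at most 22 answered queries and collapses the power to 0:

```
$ beaconkit simulate defense --n-individuals 1500 --n-snps 20000 \
      --beacon-size 100 --n-queries 5000 --replicates 100 --seed 11 \
      --budget-bits 30
{"threshold_bits": 30.0, "max_answered_queries": 22,
 "undefended": {"power": 1.0, "achieved_fpr": 0.02, ...},
 "defended":   {"power": 0.0, "achieved_fpr": 0.0, ...}}
```

`serve` exposes the same beacon over HTTP, and `network register` / `query
--registry` fan a query out across many beacons.

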