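# leascan

Sequence characterisation of nematode EST/cDNA panels for **anhydrobiosis
candidates** — in particular late embryogenesis abundant (LEA) proteins and
other highly hydrophilic, intrinsically disordered proteins that accumulate
when desiccation-tolerant animals such as the nematode *Aphelenchus avenae*
prepare to survive drying.

Given oriented EST sequences (mRNA sense: optional trans-spliced leader at
the 5' end, polyA tail at the 3' end), the pipeline answers, per transcript:

* What is the longest open reading frame, allowing for selenocysteine
  UGA read-through in candidates such as glutathione peroxidases?
* How hydrophilic is the predicted protein (GRAVY on the Eisenberg consensus
  scale), what are its M<sub>r</sub> and pI?
* Is it predicted natively unfolded on a charge–hydropathy ("Uversky") plot,
  and what fraction of it is disordered by a windowed FoldIndex-style score?
* Does it carry the Group 3 LEA signature of lysines recurring every
  11 residues (K11 periodicity)?
* Which spliced leader does it carry, and does a variant leader belong to
  the SL1 or SL2 family?

A seeded synthetic-EST generator with ground-truth manifests makes every
stage testable without any database access.

## The quantities computed

For a protein of length *N* with residues *r<sub>i</sub>*:

* **GRAVY** = (1/N) Σ h<sub>E</sub>(r<sub>i</sub>) with h<sub>E</sub> the
  Eisenberg normalised consensus hydropathy. Values below −0.43 (the GRAVY of
  bovine serum albumin) count as unusually hydrophilic.
* **Charge–hydropathy coordinates**: mean scaled hydropathy
  ⟨H⟩ ∈ [0,1] (Kyte–Doolittle rescaled by (h+4.5)/9, smoothed with a short
  window) and mean net charge ⟨R⟩ = |#K + #R − #D − #E| / N. A protein is
  predicted **natively unfolded** when ⟨H⟩ < ⟨H⟩<sub>b</sub> =
  (⟨R⟩ + 1.151)/2.785.
* **Unfoldability index** per 51-residue window,
  I = 2.785·⟨H⟩<sub>w</sub> − |⟨R⟩<sub>w</sub>| − 1.151; percent disorder is
  the fraction of residues with I < 0.
* **K11 periodicity**: maximal arithmetic chains of one residue type with
  common difference 11 (e.g. lysines at positions 38, 40, 49, 51, 60, 62 form
  two interlaced runs, {38,49,60} and {40,51,62}).
* **pI** by bisection on the Henderson–Hasselbalch net charge (EMBOSS or
  Sillero pKa tables); **M<sub>r</sub>** from average residue masses.
* **Spliced leaders**: mismatch-tolerant prefix scan against the embedded
  catalogue of 12 *A. avenae* leaders (SL1a–d, Variants 1–8); SL1/SL2 family
  assignment of variants by Needleman–Wunsch global alignment (match +1,
  mismatch −1, gap −1) against the canonical *C. elegans* SL1 and SL2.

The LEA call is an explicit rule cascade — `group3_lea` (hydrophilic AND
unfolded AND ≥1 K11 lysine run AND no Cys/Trp), `lea_like` (hydrophilic AND
unfolded), `hydrophilic_novel` (GRAVY < −0.43 OR disorder > 50%), else
`not_lea_like` — with every threshold exposed in `LeaCriteria`.

## Worked example

```sh
leascan simulate --n 5 --seed 11     # writes synthetic_seed11.fasta + manifest
leascan profile synthetic_seed11.fasta
```

prints (columns abridged):

```
id       status  sl_name   polya_len  protein_len  gravy   uversky_class  percent_disorder  k11_lysine_runs  label
syn0000  ok      Variant8  18         84           -1.166  unfolded       100.0             2                group3_lea
syn0001  ok      Variant3  12         64           0.835   folded         0.0               0                not_lea_like
syn0002  ok      Variant8  25         106          0.897   folded         0.0               0                not_lea_like
syn0003  ok      Variant7  15         97           -1.158  unfolded       100.0             2                group3_lea
syn0004  ok      Variant3  17         68           -1.144  unfolded       100.0             2                group3_lea
```

Each row is one EST: its detected spliced leader, recovered polyA-tail
length, the longest-ORF protein length, GRAVY (negative = hydrophilic),
the charge–hydropathy call, windowed percent disorder, the number of
period-11 lysine runs, and the resulting label — here the three planted
LEA-like transcripts are recovered as `group3_lea` and the two globular
decoys as `not_lea_like`.

The same from Python:

```python
import leascan as ls

p = ls.make_lea_like_protein(ls.ProteinSpec(length=85, n_k11_runs=2, seed=7))
print(round(ls.gravy(p), 2))              # -1.16  (well below -0.43)
prof = ls.physchem_profile(p)
print(round(prof.mr), round(prof.pi, 2))  # 10959 5.73
pt = ls.uversky_classify(prof.mean_scaled_hydropathy, prof.mean_net_charge)
print(pt.classification)                  # unfolded  (<H> 0.12 < boundary 0.43)
print(ls.k11_summary(p).n_lysine_runs)    # 2 interlaced K11 runs
```

## Layout

* `leascan.seq_records` — FASTA I/O, polyA trimming, translation with UGA
  read-through, ORF finding, global alignment
* `leascan.physchem` — GRAVY, M<sub>r</sub>, net charge, pI, plot coordinates
* `leascan.disorder` — charge–hydropathy classification, windowed profiles
* `leascan.periodicity` — maximal periodic runs, K11 summaries
* `leascan.spliced_leader` — leader catalogue, detection, family assignment
* `leascan.lea_classifier` — rule cascade and per-EST report
* `leascan.synthetic_data` — seeded EST/protein generators with manifests
* `leascan.cli` — `leascan profile | sl-scan | simulate | classify`

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
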