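# Packaged AMF-DB fixtures

Transcription of the curated Advanced Molecular Formulation Database used to
train the BUD regressor: experimental stability records of compounded oral
solid preparations originally collected from the Stabilis database, plus
molecular descriptors of the APIs and excipients involved (ChEMBL/PubChem
provenance).

- `amf_stability.csv` — 53 stability records. Columns: `api_name`,
  `main_excipient`, `other_excipient`, `packaging` (G = glass, Pl = plastic,
  P = paper, ND = not documented), `dose_mg`, `content_pct` (% of unit-dose
  mass), `temperature_c`, `bud_days`. Sentinels: `ND` = unknown categorical,
  `-` = missing value / no excipient.
- `amf_apis.csv` — descriptors of the 22 APIs: molecular weight `mw` (g/mol),
  `logp`, rotatable bonds `rb`, polar surface area `ps` (Å²), H-bond donors
  `hbd` / acceptors `hba`, aromatic rings `ar`. The `smiles` strings are
  standard canonical SMILES supplied as opaque identifiers; they are
  label-encoded, never parsed.
- `amf_excipients.csv` — the six excipients with the same descriptor set plus
  functional roles, predominant solid form, and supplier shelf life (years).

`mc_printed` / `msc_printed` are the composite molecule-class and
molecular-structure-class values as printed in the source tables. They are
kept as reference columns only: some printed values disagree with any single
binning convention, so the package always recomputes MC/MSC from the raw
descriptors and exposes a computed-vs-printed delta report
(`budcast.categorizer.delta_report`).
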