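# Control algorithm: the combined list of guideline-recommended first-line
# treatments and tests for BOTH lung-cancer subtypes, all used as NSCLC
# inclusion criteria with no exclusion criteria.  It serves as a comparison
# baseline and is expected to discriminate poorly.
name: "Control algorithm"
policy: inclusion_only
default_label: SCLC
eval_window_days: {pre: 90, post: 90}
combo_window_days: 21
criteria:
  # SCLC regimens, used here as inclusion rows
  - {name: "Cisplatin and etoposide", role: NSCLC_inclusion, components: [cisplatin, etoposide]}
  - {name: "Cisplatin and irinotecan", role: NSCLC_inclusion, components: [cisplatin, irinotecan]}
  - {name: "Carboplatin and etoposide", role: NSCLC_inclusion, components: [carboplatin, etoposide]}
  - {name: "Topotecan", role: NSCLC_inclusion, components: [topotecan]}
  - {name: "Cyclophosphamide, doxorubicin, and vincristine", role: NSCLC_inclusion, components: [cyclophosphamide, doxorubicin, vincristine]}
  - {name: "Carboplatin and irinotecan", role: NSCLC_inclusion, components: [carboplatin, irinotecan]}
  - {name: "Temozolomide", role: NSCLC_inclusion, components: [temozolomide]}
  - {name: "Ifosfamide", role: NSCLC_inclusion, components: [ifosfamide]}
  - {name: "Bendamustine", role: NSCLC_inclusion, components: [bendamustine]}
  # tests and NSCLC first-line treatments
  - {name: "PET scan imaging", role: NSCLC_inclusion, components: [pet_scan]}
  - {name: "Lung removal or resection surgery", role: NSCLC_inclusion, components: [lung_resection]}
  - {name: "Carboplatin and paclitaxel", role: NSCLC_inclusion, components: [carboplatin, paclitaxel]}
  - {name: "Carboplatin and gemcitabine", role: NSCLC_inclusion, components: [carboplatin, gemcitabine]}
  - {name: "Carboplatin and vinorelbine", role: NSCLC_inclusion, components: [carboplatin, vinorelbine]}
  - {name: "Cisplatin and gemcitabine", role: NSCLC_inclusion, components: [cisplatin, gemcitabine]}
  - {name: "Cisplatin and vinorelbine", role: NSCLC_inclusion, components: [cisplatin, vinorelbine]}
  - {name: "Gemcitabine and vinorelbine", role: NSCLC_inclusion, components: [gemcitabine, vinorelbine]}
  - {name: "Paclitaxel", role: NSCLC_inclusion, components: [paclitaxel]}
  - {name: "Docetaxel", role: NSCLC_inclusion, components: [docetaxel]}
  - {name: "Erlotinib", role: NSCLC_inclusion, components: [erlotinib]}
  - {name: "Gemcitabine", role: NSCLC_inclusion, components: [gemcitabine]}
  - {name: "Etoposide", role: NSCLC_inclusion, components: [etoposide]}
  - {name: "Vinorelbine", role: NSCLC_inclusion, components: [vinorelbine]}
  - {name: "Irinotecan", role: NSCLC_inclusion, components: [irinotecan]}
  - {name: "Cisplatin and docetaxel", role: NSCLC_inclusion, components: [cisplatin, docetaxel]}
  - {name: "Cisplatin and pemetrexed", role: NSCLC_inclusion, components: [cisplatin, pemetrexed]}
  - {name: "Cisplatin and paclitaxel", role: NSCLC_inclusion, components: [cisplatin, paclitaxel]}
  - {name: "Cisplatin and vinblastine", role: NSCLC_inclusion, components: [cisplatin, vinblastine]}
  - {name: "Carboplatin and pemetrexed", role: NSCLC_inclusion, components: [carboplatin, pemetrexed]}
  - {name: "Carboplatin and docetaxel", role: NSCLC_inclusion, components: [carboplatin, docetaxel]}
  - {name: "Gemcitabine and docetaxel", role: NSCLC_inclusion, components: [gemcitabine, docetaxel]}
  - {name: "Bevacizumab, carboplatin, and paclitaxel", role: NSCLC_inclusion, components: [bevacizumab, carboplatin, paclitaxel]}
  - {name: "Bevacizumab, carboplatin, and pemetrexed", role: NSCLC_inclusion, components: [bevacizumab, carboplatin, pemetrexed]}
  - {name: "Bevacizumab, cisplatin, and pemetrexed", role: NSCLC_inclusion, components: [bevacizumab, cisplatin, pemetrexed]}
  - {name: "Afatinib", role: NSCLC_inclusion, components: [afatinib]}
  - {name: "Gefitinib", role: NSCLC_inclusion, components: [gefitinib]}
  - {name: "Osimertinib", role: NSCLC_inclusion, components: [osimertinib]}
  - {name: "Crizotinib", role: NSCLC_inclusion, components: [crizotinib]}
  - {name: "Alectinib", role: NSCLC_inclusion, components: [alectinib]}
  - {name: "Ceritinib", role: NSCLC_inclusion, components: [ceritinib]}
  - {name: "Pemetrexed", role: NSCLC_inclusion, components: [pemetrexed]}
  - {name: "Abraxane (nab-paclitaxel)", role: NSCLC_inclusion, components: [nab_paclitaxel]}
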