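# NSCLC Case-Finding Algorithm: first-line treatments-and-tests criteria.
# SCLC-indicative regimens are exclusion criteria (their presence vetoes an
# NSCLC label); NSCLC-indicative tests and first-line treatments are
# inclusion criteria.  Single agents used for both subtypes (paclitaxel,
# docetaxel, gemcitabine, etoposide, vinorelbine, irinotecan, pemetrexed)
# are deliberately absent from the inclusion list — they appear only in the
# control algorithm.
name: "NSCLC Case-Finding Algorithm"
policy: exclusion_first
default_label: SCLC
eval_window_days: {pre: 90, post: 90}
combo_window_days: 21
criteria:
  # --- small cell lung cancer exclusion criteria ---
  - {name: "Cisplatin and etoposide", role: SCLC_exclusion, components: [cisplatin, etoposide]}
  - {name: "Cisplatin and irinotecan", role: SCLC_exclusion, components: [cisplatin, irinotecan]}
  - {name: "Carboplatin and etoposide", role: SCLC_exclusion, components: [carboplatin, etoposide]}
  - {name: "Topotecan", role: SCLC_exclusion, components: [topotecan]}
  - {name: "Cyclophosphamide, doxorubicin, and vincristine", role: SCLC_exclusion, components: [cyclophosphamide, doxorubicin, vincristine]}
  - {name: "Carboplatin and irinotecan", role: SCLC_exclusion, components: [carboplatin, irinotecan]}
  - {name: "Temozolomide", role: SCLC_exclusion, components: [temozolomide]}
  - {name: "Ifosfamide", role: SCLC_exclusion, components: [ifosfamide]}
  - {name: "Bendamustine", role: SCLC_exclusion, components: [bendamustine]}
  # --- non-small cell lung cancer inclusion criteria ---
  - {name: "PET scan imaging", role: NSCLC_inclusion, components: [pet_scan]}
  - {name: "Lung removal or resection surgery", role: NSCLC_inclusion, components: [lung_resection]}
  - {name: "Carboplatin and paclitaxel", role: NSCLC_inclusion, components: [carboplatin, paclitaxel]}
  - {name: "Carboplatin and gemcitabine", role: NSCLC_inclusion, components: [carboplatin, gemcitabine]}
  - {name: "Carboplatin and vinorelbine", role: NSCLC_inclusion, components: [carboplatin, vinorelbine]}
  - {name: "Cisplatin and gemcitabine", role: NSCLC_inclusion, components: [cisplatin, gemcitabine]}
  - {name: "Cisplatin and vinorelbine", role: NSCLC_inclusion, components: [cisplatin, vinorelbine]}
  - {name: "Gemcitabine and vinorelbine", role: NSCLC_inclusion, components: [gemcitabine, vinorelbine]}
  - {name: "Erlotinib", role: NSCLC_inclusion, components: [erlotinib]}
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
  - {name: "Abraxane (nab-paclitaxel)", role: NSCLC_inclusion, components: [nab_paclitaxel]}
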