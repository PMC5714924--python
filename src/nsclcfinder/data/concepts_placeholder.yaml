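# PLACEHOLDER concept -> code map.
#
# The licensed GPI / HCPCS / CPT / ICD procedure code dictionaries that
# identify each treatment and test concept in real adjudicated claims are
# proprietary and are NOT shipped with this package.  Every code below is a
# clearly synthetic stand-in (prefix "PLC-") so the pipeline is runnable
# end-to-end on synthetic data.  Replace this file with your organisation's
# code lists before running against real claims; the matching engine only
# cares that each concept maps to a non-empty set of (system, code) pairs.
concepts:
  cisplatin:
    - {system: GPI, code: "PLC-GPI-CISPLATIN"}
    - {system: HCPCS, code: "PLC-J-CISPLATIN"}
  carboplatin:
    - {system: GPI, code: "PLC-GPI-CARBOPLATIN"}
    - {system: HCPCS, code: "PLC-J-CARBOPLATIN"}
  etoposide:
    - {system: GPI, code: "PLC-GPI-ETOPOSIDE"}
    - {system: HCPCS, code: "PLC-J-ETOPOSIDE"}
  irinotecan:
    - {system: GPI, code: "PLC-GPI-IRINOTECAN"}
    - {system: HCPCS, code: "PLC-J-IRINOTECAN"}
  topotecan:
    - {system: GPI, code: "PLC-GPI-TOPOTECAN"}
    - {system: HCPCS, code: "PLC-J-TOPOTECAN"}
  cyclophosphamide:
    - {system: GPI, code: "PLC-GPI-CYCLOPHOSPHAMIDE"}
    - {system: HCPCS, code: "PLC-J-CYCLOPHOSPHAMIDE"}
  doxorubicin:
    - {system: GPI, code: "PLC-GPI-DOXORUBICIN"}
    - {system: HCPCS, code: "PLC-J-DOXORUBICIN"}
  vincristine:
    - {system: GPI, code: "PLC-GPI-VINCRISTINE"}
    - {system: HCPCS, code: "PLC-J-VINCRISTINE"}
  temozolomide:
    - {system: GPI, code: "PLC-GPI-TEMOZOLOMIDE"}
    - {system: HCPCS, code: "PLC-J-TEMOZOLOMIDE"}
  ifosfamide:
    - {system: GPI, code: "PLC-GPI-IFOSFAMIDE"}
    - {system: HCPCS, code: "PLC-J-IFOSFAMIDE"}
  bendamustine:
    - {system: GPI, code: "PLC-GPI-BENDAMUSTINE"}
    - {system: HCPCS, code: "PLC-J-BENDAMUSTINE"}
  paclitaxel:
    - {system: GPI, code: "PLC-GPI-PACLITAXEL"}
    - {system: HCPCS, code: "PLC-J-PACLITAXEL"}
  nab_paclitaxel:
    - {system: GPI, code: "PLC-GPI-NABPACLITAXEL"}
    - {system: HCPCS, code: "PLC-J-NABPACLITAXEL"}
  docetaxel:
    - {system: GPI, code: "PLC-GPI-DOCETAXEL"}
    - {system: HCPCS, code: "PLC-J-DOCETAXEL"}
  gemcitabine:
    - {system: GPI, code: "PLC-GPI-GEMCITABINE"}
    - {system: HCPCS, code: "PLC-J-GEMCITABINE"}
  vinorelbine:
    - {system: GPI, code: "PLC-GPI-VINORELBINE"}
    - {system: HCPCS, code: "PLC-J-VINORELBINE"}
  vinblastine:
    - {system: GPI, code: "PLC-GPI-VINBLASTINE"}
    - {system: HCPCS, code: "PLC-J-VINBLASTINE"}
  pemetrexed:
    - {system: GPI, code: "PLC-GPI-PEMETREXED"}
    - {system: HCPCS, code: "PLC-J-PEMETREXED"}
  bevacizumab:
    - {system: GPI, code: "PLC-GPI-BEVACIZUMAB"}
    - {system: HCPCS, code: "PLC-J-BEVACIZUMAB"}
  erlotinib:
    - {system: GPI, code: "PLC-GPI-ERLOTINIB"}
  afatinib:
    - {system: GPI, code: "PLC-GPI-AFATINIB"}
  gefitinib:
    - {system: GPI, code: "PLC-GPI-GEFITINIB"}
  osimertinib:
    - {system: GPI, code: "PLC-GPI-OSIMERTINIB"}
  crizotinib:
    - {system: GPI, code: "PLC-GPI-CRIZOTINIB"}
  alectinib:
    - {system: GPI, code: "PLC-GPI-ALECTINIB"}
  ceritinib:
    - {system: GPI, code: "PLC-GPI-CERITINIB"}
  pet_scan:
    - {system: CPT, code: "PLC-CPT-PETSCAN"}
    - {system: HCPCS, code: "PLC-G-PETSCAN"}
  lung_resection:
    - {system: CPT, code: "PLC-CPT-LUNGRESECT"}
    - {system: ICD10_PROC, code: "PLC-ICD10P-LUNGRESECT"}
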