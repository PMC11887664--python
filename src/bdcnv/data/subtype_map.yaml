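# Pediatric cancer subtype grouping by ICD-9/ICD-10 code prefix.
# Seven groups; "other" is the fallback for cancer codes matching no rule.
# The code ranges are a reconstruction of the usual seven-group scheme and
# are meant to be edited per study.
# Matching: a diagnosis code matches a rule when it starts with one of the
# prefixes (dots ignored for ICD-9 integer prefixes); the first matching
# rule in order wins for single-assignment outputs.
categories:
  - name: brain_nervous
    prefixes: ["191", "192", "C70", "C71", "C72"]
  - name: bone_connective_soft_tissue
    prefixes: ["170", "171", "C40", "C41", "C49"]
  - name: respiratory_digestive
    prefixes: ["15", "160", "161", "162", "163", "164", "165",
               "C15", "C16", "C17", "C18", "C19", "C20", "C21", "C22",
               "C23", "C24", "C25", "C26", "C30", "C31", "C32", "C33",
               "C34", "C37", "C38", "C39"]
  - name: endocrine_gland
    prefixes: ["193", "194", "C73", "C74", "C75"]
  - name: kidney
    prefixes: ["189", "C64", "C65"]
  - name: eye
    prefixes: ["190", "C69"]
fallback: other
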