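# Control-region typing rules for Lacertidae: 5 general types, 21 subtypes.
#
# The published scheme defines the subtypes only schematically, so this table
# is an explicit reconstruction following the stated criteria: general types
# by element presence and anormal-TR placement (anormal = a tandem repeat
# between two conserved elements), subtypes within I-IV by the normal-TR
# placement pattern (before TAS1 / after CSB3), Type V by which elements are
# missing or displaced.  Edit or replace this file to change the typology.
#
# Rule semantics: "presence" is the exact set of elements present; order_ok /
# anormal / normal constrain the profile exactly when given, and are
# unconstrained when omitted.  The highest-priority satisfied rule wins.

rules:
  # --- Type I: full canonical scaffold, no anormal TR --------------------
  - {label: I-1, general_type: I, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [], normal: []}
  - {label: I-2, general_type: I, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [], normal: [after_CSB3]}
  - {label: I-3, general_type: I, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [], normal: [before_TAS1]}
  - {label: I-4, general_type: I, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [], normal: [before_TAS1, after_CSB3]}

  # --- Type II: anormal TR between CSB1 and CSB2 (Darevskia pattern) -----
  - {label: II-1, general_type: II, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [between_CSB1_CSB2], normal: []}
  - {label: II-2, general_type: II, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [between_CSB1_CSB2], normal: [before_TAS1]}
  - {label: II-3, general_type: II, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [between_CSB1_CSB2], normal: [before_TAS1, after_CSB3]}

  # --- Type III: anormal TR between TAS2 and CSB1 ------------------------
  - {label: III-1, general_type: III, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [between_TAS2_CSB1], normal: [before_TAS1]}

  # --- Type IV: anormal TR between CSB2 and CSB3 -------------------------
  - {label: IV-1, general_type: IV, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [between_CSB2_CSB3], normal: []}
  - {label: IV-2, general_type: IV, priority: 100,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: true,
     anormal: [between_CSB2_CSB3], normal: [after_CSB3]}

  # --- Type V: defective scaffold, keyed to the missing/displaced part ---
  - {label: V-1, general_type: V, priority: 10,
     presence: [CSB2, CSB3]}
  - {label: V-2, general_type: V, priority: 10,
     presence: [TAS2, CSB1, CSB2, CSB3]}
  - {label: V-3, general_type: V, priority: 10,
     presence: [TAS1, CSB1, CSB2, CSB3]}
  - {label: V-4, general_type: V, priority: 10,
     presence: [TAS1, TAS2, CSB2, CSB3]}
  - {label: V-5, general_type: V, priority: 10,
     presence: [TAS1, TAS2, CSB1, CSB3]}
  - {label: V-6, general_type: V, priority: 10,
     presence: [TAS1, TAS2, CSB1, CSB2]}
  - {label: V-7, general_type: V, priority: 10,
     presence: [CSB1, CSB2, CSB3]}
  - {label: V-8, general_type: V, priority: 10,
     presence: [TAS1, TAS2, CSB1]}
  - {label: V-9, general_type: V, priority: 10,
     presence: [TAS1, TAS2, CSB3]}
  - {label: V-10, general_type: V, priority: 10,
     presence: [TAS1, TAS2, CSB1, CSB2, CSB3], order_ok: false}
  - {label: V-11, general_type: V, priority: 10,
     presence: [CSB3]}
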