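schema_version: 1
name: trispecific-invitro
collision_factor: 0.002
bridges_per_synapse: 5.0
volume: 0.2
reference_volume: 0.2
arms:
- name: CD3
  kon: 0.2
  KD: 1.0
- name: CD28
  kon: 0.1
  KD: 5.0
- name: CD38
  kon: 0.5
  KD: 0.3
receptors:
- name: CD3
  expressed_on:
    CD4_naive: 60000.0
    CD4_EM: 60000.0
    CD4_active: 60000.0
    CD8_naive: 60000.0
    CD8_EM: 60000.0
    CD8_active: 60000.0
  drug_arm: CD3
- name: CD28
  expressed_on:
    CD4_naive: 30000.0
    CD4_EM: 30000.0
    CD4_active: 30000.0
    CD8_naive: 30000.0
    CD8_EM: 30000.0
    CD8_active: 30000.0
    MM: 10000.0
  drug_arm: CD28
- name: CD38
  expressed_on:
    MM: 129000.0
    PBMC: 10000.0
  drug_arm: CD38
cells:
- name: CD4_naive
  lineage: CD4-T
  activation_state: naive
  receptors:
  - CD3
  - CD28
  proliferation_rate: 0.001
  degradation_rate: 0.002
  can_kill: false
  killable: false
  initial_count: 80000.0
- name: CD4_EM
  lineage: CD4-T
  activation_state: effector-memory
  receptors:
  - CD3
  - CD28
  proliferation_rate: 0.002
  degradation_rate: 0.002
  can_kill: false
  killable: false
  initial_count: 70000.0
- name: CD4_active
  lineage: CD4-T
  activation_state: active
  receptors:
  - CD3
  - CD28
  proliferation_rate: 0.03
  degradation_rate: 0.01
  can_kill: true
  killable: false
  initial_count: 10000.0
- name: CD8_naive
  lineage: CD8-T
  activation_state: naive
  receptors:
  - CD3
  - CD28
  proliferation_rate: 0.001
  degradation_rate: 0.002
  can_kill: false
  killable: false
  initial_count: 40000.0
- name: CD8_EM
  lineage: CD8-T
  activation_state: effector-memory
  receptors:
  - CD3
  - CD28
  proliferation_rate: 0.002
  degradation_rate: 0.002
  can_kill: false
  killable: false
  initial_count: 36000.0
- name: CD8_active
  lineage: CD8-T
  activation_state: active
  receptors:
  - CD3
  - CD28
  proliferation_rate: 0.03
  degradation_rate: 0.01
  can_kill: true
  killable: false
  initial_count: 4000.0
- name: MM
  lineage: tumor
  activation_state: not-applicable
  receptors:
  - CD38
  - CD28
  proliferation_rate: 0.02
  degradation_rate: 0.005
  can_kill: false
  killable: true
  initial_count: 10000.0
- name: PBMC
  lineage: PBMC
  activation_state: not-applicable
  receptors:
  - CD38
  proliferation_rate: 0.0
  degradation_rate: 0.01
  can_kill: false
  killable: true
  initial_count: 120000.0
cytokines:
- name: TNFa
  producers:
  - cell: CD4_active
    rate: 2000.0
    in_synapse_only: false
  - cell: CD8_active
    rate: 2000.0
    in_synapse_only: false
- name: IFNg
  producers:
  - cell: CD4_active
    rate: 4000.0
    in_synapse_only: false
  - cell: CD8_active
    rate: 4000.0
    in_synapse_only: false
- name: IL6
  producers:
  - cell: CD4_active
    rate: 1000.0
    in_synapse_only: false
  - cell: CD8_active
    rate: 1000.0
    in_synapse_only: false
  - cell: PBMC
    rate: 800.0
    in_synapse_only: true
- name: IL10
  producers:
  - cell: PBMC
    rate: 500.0
    in_synapse_only: true
activation:
  k_act_EM: 0.2
  k_act_naive: 0.3
  Km_CD3_bound: 500.0
  Km_CD28_bound: 200.0
  cd3_receptor: CD3
  cd28_receptor: CD28
killing:
- killer: CD4-T
  victim: PBMC
  rate: 0.04
- killer: CD4-T
  victim: tumor
  rate: 0.1
- killer: CD8-T
  victim: PBMC
  rate: 0.15
- killer: CD8-T
  victim: tumor
  rate: 0.4
resistance_rate: 0.05
soluble_antigen:
  name: sCD38
  shedding_sources:
  - MM
  shedding_rate: 50.0
  kon: 0.1
  KD: 10.0
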