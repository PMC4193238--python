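# Memory-model parameters, 4th-generation kernel (bytes).
generation: 4g
m_n: 1100        # one neuron object (iaf_psc_alpha)
m0_n: 0          # overhead per neuron: eliminated by the sparse node array
mplus_n: 24      # overhead per local neuron (pointer + long in the node array)
mempty_n: 0
m_stat_c: 16     # one static_synapse_hpc object
m_stdp_c: 24     # one stdp_pl_synapse_hom_hpc object
m0_c: 0.3333333333333333   # sparse presence table, per neuron
m1_c: 24         # overhead per neuron with one local target (HomConnector)
mgt1_c: 128      # overhead per neuron with more than one local target
mempty_c: 0
beta: 0.8
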