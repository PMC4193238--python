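# Memory-model parameters, 3rd-generation kernel (bytes).
# m0_n and m0_c are the per-neuron sparse-table costs; the nominal 0.33 B
# is stored as the exact 1/3 B it rounds.
generation: 3g
m_n: 1100        # one neuron object (iaf_psc_alpha)
m0_n: 0.3333333333333333   # overhead per neuron (sparse table of nodes)
mplus_n: 16      # overhead per local neuron
mempty_n: 0      # overhead per non-local neuron
m_stat_c: 48     # one static_synapse object
m_stdp_c: 48     # one stdp_pl_synapse object
m0_c: 0.3333333333333333   # overhead per neuron (sparse table of connections)
m1_c: 96         # overhead per neuron with one local target
mgt1_c: 160      # overhead per neuron with more than one local target
mempty_c: 0      # overhead per neuron without local targets
beta: 0.8        # excitatory fraction
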