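# Post-hoc override rules applied to model sentence predictions.
# n2p patterns flip model-absent sentences to present when they match;
# p2n rules flip model-present sentences to absent when the trigger
# matches and the blocking term is not indicated in the sentence.
n2p:
  - '(instructed|reviewed|discussed).*(use\sof\sMDI|use\sof\sspacer|use\sof\snebulizer|use\sof\sinhaler)'
p2n:
  - trigger: '(discussed|discussion)'
    blocker: 'technique'
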