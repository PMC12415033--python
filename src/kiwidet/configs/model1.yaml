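depth: 0.33
width: 0.125
nc: 1
imgsz: 640
max_channels: 1024
name: model1
dualhet:
  enabled: false
  p: 4
ccfm:
  enabled: false
loss:
  box: ciou
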