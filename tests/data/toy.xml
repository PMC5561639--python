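<?xml version="1.0" encoding="utf-8"?>
<labels xmlns="http://mulan.sourceforge.net/labels">
  <label name="l1"/>
  <label name="l2"/>
</labels>
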