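<?xml version="1.0" encoding="UTF-8"?>
<!-- SYNTHETIC steep inward-rectifier-like potassium channel (not a database
     Kir2.1 model): conductance decreases with depolarization, opening the
     channel at hyperpolarized voltages.  Used for amphibian bistability
     demonstrations. -->
<channelml units="Physiological Units">
  <channel_type name="kir_synthetic">
    <current_voltage_relation cond_law="ohmic" ion="K">
      <q10_settings q10_factor="3" experimental_temp="23"/>
      <gate name="r" instances="1" role="activation">
        <steady_state expr_form="sigmoid" midpoint="-80" slope="-0.15"/>
        <time_course expr_form="constant" tau="1.0"/>
      </gate>
    </current_voltage_relation>
  </channel_type>
</channelml>
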