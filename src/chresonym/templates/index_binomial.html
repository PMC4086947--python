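{% extends "base.html" %}
{% block title %}Binomial and compound name index{% endblock %}
{% block heading %}Binomial and compound name index{% endblock %}
{% block content %}
<ul class="binomial-index">
{% for entry in entries %}
  <li><a href="{{ links.binomial(entry.name) }}"><em>{{ entry.name }}</em></a></li>
{% endfor %}
</ul>
{% endblock %}
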